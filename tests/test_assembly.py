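"""Glycoproteoform enumeration, pairing and envelope rendering/comparison."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from mpoglyco.assembly import (
    MassEnvelope,
    VariantFactor,
    compare_envelopes,
    enumerate_protomers,
    pair_diprotomers,
    render_envelope,
)
from mpoglyco.glycans import glycan_mass, parse_shorthand
from mpoglyco.profiles import SiteGlycoprofile


def _profiles(counts):
    """One profile per site with the requested number of equal-weight glycoforms."""
    codes = ["M2F", "M3F", "M5", "M6", "GlcNAc1", "FA1", "unoccupied"]
    profs = []
    for s, k in enumerate(counts):
        ab = {codes[i]: 1.0 / k for i in range(k)}
        profs.append(SiteGlycoprofile(site=s + 1, abundances=ab))
    return profs


def test_enumeration_count_is_product_of_site_choices():
    variants, pruned = enumerate_protomers(_profiles([3, 2, 2, 1, 2]), 60000.0, theta=0.0)
    assert len(variants) == 3 * 2 * 2 * 1 * 2
    assert pruned == 0.0
    assert sum(v.weight for v in variants) == pytest.approx(1.0)


def test_enumeration_with_factors_and_weight_conservation():
    factors = [
        VariantFactor("oxidation", {"0": (0.6, 0.0), "1": (0.4, 15.9994)}),
        VariantFactor("truncation", {"full": (0.9, 0.0), "desGly": (0.1, -57.05)}),
    ]
    variants, pruned = enumerate_protomers(_profiles([2, 2]), 60000.0, factors=factors, theta=0.0)
    assert len(variants) == 2 * 2 * 2 * 2
    assert sum(v.weight for v in variants) + pruned == pytest.approx(1.0)


def test_pruning_reports_lost_weight():
    profs = [SiteGlycoprofile(site=1, abundances={"M5": 0.999, "GlcNAc1": 0.001})]
    variants, pruned = enumerate_protomers(profs, 60000.0, theta=0.01)
    assert len(variants) == 1
    assert pruned == pytest.approx(0.001)
    assert sum(v.weight for v in variants) + pruned == pytest.approx(1.0)


def test_single_variant_mass_is_hand_summed():
    base = 65000.0
    profs = [
        SiteGlycoprofile(site=323, abundances={"M2F": 1.0}),
        SiteGlycoprofile(site=355, abundances={"M6": 1.0}),
    ]
    variants, _ = enumerate_protomers(profs, base, theta=0.0, scale="average")
    assert len(variants) == 1
    expected = (
        base
        + glycan_mass(parse_shorthand("M2F").composition, "conjugated", "average")
        + glycan_mass(parse_shorthand("M6").composition, "conjugated", "average")
    )
    assert variants[0].mass == pytest.approx(expected, abs=1e-9)


def test_unoccupied_contributes_zero_mass():
    profs = [SiteGlycoprofile(site=729, abundances={"unoccupied": 1.0})]
    variants, _ = enumerate_protomers(profs, 1000.0, theta=0.0)
    assert variants[0].mass == 1000.0


def test_empty_profile_raises():
    with pytest.raises(ValueError):
        enumerate_protomers([], 1000.0)


def test_diprotomer_pair_count_closed_form():
    protomers, _ = enumerate_protomers(_profiles([3, 2, 2, 1, 2]), 60000.0, theta=0.0)
    assert len(protomers) == 24
    dips, pruned = pair_diprotomers(protomers, theta=0.0)
    assert len(dips) == 24 * 25 // 2
    assert pruned == 0.0
    assert sum(d.weight for d in dips) == pytest.approx(1.0)


def test_two_equal_protomers_pair_binomially():
    protomers, _ = enumerate_protomers(
        [SiteGlycoprofile(site=1, abundances={"M5": 0.5, "M6": 0.5})], 60000.0, theta=0.0
    )
    dips, _ = pair_diprotomers(protomers, theta=0.0)
    weights = sorted(d.weight for d in dips)
    assert weights == pytest.approx([0.25, 0.25, 0.5])


def test_diprotomer_mass_includes_bridge_correction():
    protomers, _ = enumerate_protomers(
        [SiteGlycoprofile(site=1, abundances={"M5": 1.0})], 60000.0, theta=0.0
    )
    dips, _ = pair_diprotomers(protomers, theta=0.0, scale="average")
    assert dips[0].mass == pytest.approx(2 * protomers[0].mass - 2 * 1.00794)


def test_envelope_single_variant_apex():
    protomers, _ = enumerate_protomers(
        [SiteGlycoprofile(site=1, abundances={"M5": 1.0})], 144000.0, theta=0.0
    )
    env = render_envelope(protomers, fwhm=200.0)
    spacing = env.grid[1] - env.grid[0]
    assert abs(env.apex - protomers[0].mass) <= spacing


def test_envelope_resolved_doublet():
    profs = [SiteGlycoprofile(site=1, abundances={"GlcNAc1": 0.5, "M6": 0.5})]
    variants, _ = enumerate_protomers(profs, 144000.0, theta=0.0)
    env = render_envelope(variants, fwhm=100.0)
    masses = sorted(v.mass for v in variants)
    assert masses[1] - masses[0] > 10 * 100.0
    peaks = [
        env.grid[i]
        for i in range(1, len(env.grid) - 1)
        if env.intensity[i] > env.intensity[i - 1]
        and env.intensity[i] >= env.intensity[i + 1]
        and env.intensity[i] > 0.5
    ]
    assert len(peaks) == 2
    spacing = env.grid[1] - env.grid[0]
    assert abs(peaks[0] - masses[0]) <= 2 * spacing
    assert abs(peaks[1] - masses[1]) <= 2 * spacing


def test_envelope_matches_dense_bruteforce_oracle():
    masses = np.array([100000.0, 100180.0, 100320.0])
    weights = np.array([0.2, 0.5, 0.3])
    from mpoglyco.assembly import ProteoformVariant

    variants = [
        ProteoformVariant(glycoforms=(), factors=(), mass=m, weight=w)
        for m, w in zip(masses, weights)
    ]
    fwhm = 150.0
    sigma = fwhm / (2 * math.sqrt(2 * math.log(2)))
    env = render_envelope(variants, fwhm=fwhm, grid_spacing=1.0)
    dense = np.zeros_like(env.grid)
    for m, w in zip(masses, weights):
        dense += w * np.exp(-((env.grid - m) ** 2) / (2 * sigma**2))
    dense /= dense.max()
    assert np.max(np.abs(env.intensity - dense)) < 0.01
    assert abs(env.apex - env.grid[np.argmax(dense)]) <= 2.0


def test_symmetric_ensemble_apex_is_weighted_mean():
    from mpoglyco.assembly import ProteoformVariant

    variants = [
        ProteoformVariant((), (), 100000.0, 0.25),
        ProteoformVariant((), (), 100100.0, 0.5),
        ProteoformVariant((), (), 100200.0, 0.25),
    ]
    env = render_envelope(variants, fwhm=300.0)
    mean_mass = sum(v.mass * v.weight for v in variants)
    spacing = env.grid[1] - env.grid[0]
    assert abs(env.apex - mean_mass) <= spacing


def test_compare_identical_envelopes():
    from mpoglyco.assembly import ProteoformVariant

    variants = [ProteoformVariant((), (), 144000.0, 1.0)]
    env = render_envelope(variants, fwhm=200.0)
    res = compare_envelopes(env, env.grid, env.intensity)
    assert res["apex_offset"] == 0.0
    assert res["overlap"] == pytest.approx(1.0, abs=1e-3)


def test_compare_shifted_envelope_reports_offset():
    from mpoglyco.assembly import ProteoformVariant

    env = render_envelope([ProteoformVariant((), (), 144000.0, 1.0)], fwhm=200.0)
    delta = 500.0
    res = compare_envelopes(env, env.grid + delta, env.intensity)
    assert res["apex_offset"] == pytest.approx(-delta, abs=2.0)


def test_gaussian_overlap_matches_closed_form():
    from mpoglyco.assembly import ProteoformVariant

    fwhm = 200.0
    sigma = fwhm / (2 * math.sqrt(2 * math.log(2)))
    d = 150.0
    env1 = render_envelope([ProteoformVariant((), (), 144000.0, 1.0)], fwhm=fwhm, grid_spacing=0.5)
    env2 = render_envelope([ProteoformVariant((), (), 144000.0 + d, 1.0)], fwhm=fwhm, grid_spacing=0.5)
    res = compare_envelopes(env1, env2.grid, env2.intensity)
    expected = 2.0 * norm.cdf(-d / (2.0 * sigma))
    assert res["overlap"] == pytest.approx(expected, abs=0.01)


def test_disjoint_ranges_overlap_zero():
    from mpoglyco.assembly import ProteoformVariant

    env = render_envelope([ProteoformVariant((), (), 1000.0, 1.0)], fwhm=10.0)
    with pytest.warns(UserWarning, match="disjoint"):
        res = compare_envelopes(env, np.array([5000.0, 5001.0]), np.array([1.0, 1.0]))
    assert res["overlap"] == 0.0


def test_envelope_grid_invariants():
    from mpoglyco.assembly import ProteoformVariant

    env = render_envelope([ProteoformVariant((), (), 1000.0, 1.0)], fwhm=10.0)
    assert np.all(np.diff(env.grid) > 0)
    assert env.intensity.max() == pytest.approx(1.0)
    assert np.all(env.intensity >= 0)
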