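"""Profile normalisation, occupancy, Endo H transform, correlations, t-tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpoglyco.profiles import (
    SiteGlycoprofile,
    endoh_transform,
    enrichment_test,
    occupancy,
    profile_correlation,
    profile_from_auc_table,
)


def test_normalisation_from_auc_rows():
    profs = profile_from_auc_table([(323, "M2F", "1", 80.0), (323, "M3F", "1", 20.0)])
    assert len(profs) == 1
    assert profs[0].abundances == pytest.approx({"M2F": 0.8, "M3F": 0.2})


def test_unoccupied_rows_normalise():
    profs = profile_from_auc_table(
        [(729, "unoccupied", "1", 50.0), (729, "GlcNAc1", "1", 50.0)]
    )
    assert profs[0].abundances == pytest.approx({"unoccupied": 0.5, "GlcNAc1": 0.5})


def test_identical_replicates_have_zero_sd():
    rows = [
        (323, "M2F", rep, 80.0)
        for rep in "123"
    ] + [(323, "M3F", rep, 20.0) for rep in "123"]
    profs = profile_from_auc_table(rows)
    assert len(profs) == 3
    vals = [p.abundance("M2F") for p in profs]
    assert np.std(vals) == pytest.approx(0.0, abs=1e-12)


def test_all_zero_auc_raises():
    with pytest.raises(ValueError, match="all-zero"):
        profile_from_auc_table([(323, "M2F", "1", 0.0)])


def test_invalid_code_raises():
    with pytest.raises(Exception):
        profile_from_auc_table([(323, "NOTACODE", "1", 1.0)])


@pytest.mark.parametrize(
    "abundances,expected",
    [
        ({"unoccupied": 0.3, "GlcNAc1": 0.7}, 0.7),
        ({"M5": 1.0}, 1.0),
        ({"unoccupied": 1.0}, 0.0),
    ],
)
def test_occupancy(abundances, expected):
    p = SiteGlycoprofile(site=729, abundances=abundances)
    assert occupancy(p) == pytest.approx(expected)


@pytest.mark.parametrize(
    "before,after",
    [
        ({"M6": 1.0}, {"GlcNAc1": 1.0}),
        ({"M2F": 1.0}, {"M2F": 1.0}),
        ({"M5": 0.5, "GlcNAc1": 0.5}, {"GlcNAc1": 1.0}),
        (
            {"M5": 0.3, "M2F": 0.4, "unoccupied": 0.3},
            {"GlcNAc1": 0.3, "M2F": 0.4, "unoccupied": 0.3},
        ),
    ],
)
def test_endoh_transform_mapping(before, after):
    p = SiteGlycoprofile(site=355, abundances=before)
    assert endoh_transform(p).abundances == pytest.approx(after)


@st.composite
def profiles_(draw):
    codes = draw(
        st.lists(
            st.sampled_from(
                ["M5", "M6", "M2F", "M3F", "GlcNAc1", "GlcNAc1F", "FA1", "FA1G1S1", "unoccupied"]
            ),
            min_size=1,
            max_size=6,
            unique=True,
        )
    )
    raw = draw(
        st.lists(
            st.floats(0.01, 1.0, allow_nan=False), min_size=len(codes), max_size=len(codes)
        )
    )
    total = sum(raw)
    return SiteGlycoprofile(site=355, abundances={c: v / total for c, v in zip(codes, raw)})


@given(profiles_())
@settings(max_examples=150, deadline=None)
def test_endoh_transform_idempotent_and_normalised(p):
    once = endoh_transform(p)
    twice = endoh_transform(once)
    assert sum(once.abundances.values()) == pytest.approx(1.0, abs=1e-9)
    assert twice.abundances == pytest.approx(once.abundances)


def test_profile_correlation_self_is_one(simple_profile):
    assert profile_correlation(simple_profile, simple_profile) == pytest.approx(1.0)


def test_profile_correlation_hand_computed():
    p = SiteGlycoprofile(site=1, abundances={"M5": 0.8, "M6": 0.1, "GlcNAc1": 0.1})
    q = SiteGlycoprofile(site=1, abundances={"M5": 0.1, "M6": 0.8, "GlcNAc1": 0.1})
    assert profile_correlation(p, q) == pytest.approx(-0.5)


def test_profile_correlation_perfect_anticorrelation():
    # abundances in arithmetic progression, reversed: exactly r = -1
    a, b, c = 0.5, 1.0 / 3.0, 1.0 / 6.0
    p = SiteGlycoprofile(site=1, abundances={"M5": a, "M6": b, "GlcNAc1": c})
    q = SiteGlycoprofile(site=1, abundances={"M5": c, "M6": b, "GlcNAc1": a})
    assert profile_correlation(p, q) == pytest.approx(-1.0)


def test_profile_correlation_reversed_rank_strongly_negative():
    p = SiteGlycoprofile(site=1, abundances={"M5": 0.6, "M6": 0.3, "GlcNAc1": 0.1})
    q = SiteGlycoprofile(site=1, abundances={"M5": 0.1, "M6": 0.3, "GlcNAc1": 0.6})
    assert profile_correlation(p, q) == pytest.approx(-0.9736842)


def test_profile_correlation_symmetric(simple_profile):
    q = SiteGlycoprofile(site=323, abundances={"M2F": 0.1, "M3F": 0.6, "FA1": 0.3})
    assert profile_correlation(simple_profile, q) == pytest.approx(
        profile_correlation(q, simple_profile)
    )


def test_profile_correlation_union_of_keys():
    # keys absent from one profile count as zero there
    p = SiteGlycoprofile(site=1, abundances={"M5": 0.5, "M6": 0.5})
    q = SiteGlycoprofile(site=1, abundances={"M5": 0.5, "GlcNAc1": 0.5})
    r = profile_correlation(p, q)
    assert -1.0 <= r <= 1.0


def test_profile_correlation_degenerate_raises():
    p = SiteGlycoprofile(site=1, abundances={"M5": 1 / 3, "M6": 1 / 3, "GlcNAc1": 1 / 3})
    with pytest.raises(ValueError, match="variance"):
        profile_correlation(p, p)


def test_enrichment_test_identical_groups():
    res = enrichment_test([0.1, 0.1, 0.1], [0.1, 0.1, 0.1])
    assert res["difference"] == 0.0
    assert res["p"] == 1.0
    res2 = enrichment_test([1, 2, 3], [1, 2, 3])
    assert res2["difference"] == 0.0


def test_enrichment_test_p_shrinks_with_jitter():
    rng = np.random.default_rng(0)
    ps = []
    for eps in (0.1, 0.01, 0.001):
        a = list(rng.normal(0.0, eps, 4))
        b = list(rng.normal(1.0, eps, 4))
        ps.append(enrichment_test(a, b)["p"])
    assert ps[0] > ps[1] > ps[2]


def test_enrichment_test_requires_replicates():
    with pytest.raises(ValueError):
        enrichment_test([1.0], [1.0, 2.0])
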