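"""Shrake-Rupley SASA against analytic, Monte-Carlo and independent oracles."""

import math

import numpy as np
import pytest

from conftest import monte_carlo_sasa, spherical_cap_pair_area
from mpoglyco.structure import (
    StructureModel,
    dimer_occlusion,
    golden_spiral_points,
    read_pdb,
    relative_accessibility,
    sasa,
    sequon_accessibility,
    write_pdb,
)
from mpoglyco.synth import gen_dimer, gen_globular_cluster, gen_sphere_cluster


def test_isolated_sphere_area_is_exact():
    model = gen_sphere_cluster([(0.0, 0.0, 0.0)], [2.0])
    res = sasa(model, probe=5.0, n_points=960)
    assert res.total_area == pytest.approx(4.0 * math.pi * 49.0, rel=1e-12)
    assert res.total_area == pytest.approx(615.75, abs=0.01)


def test_far_separated_spheres_unoccluded():
    model = gen_sphere_cluster([(0.0, 0.0, 0.0), (30.0, 0.0, 0.0)], [2.0, 2.0])
    res = sasa(model, probe=5.0, n_points=960)
    iso = 4.0 * math.pi * 49.0
    assert res.atom_area == pytest.approx([iso, iso], rel=1e-12)


@pytest.mark.parametrize("d", [4.0, 8.0, 11.0])
def test_two_sphere_cap_formula_within_one_percent(d):
    r1, r2, probe = 2.0, 1.5, 5.0
    model = gen_sphere_cluster([(0.0, 0.0, 0.0), (d, 0.0, 0.0)], [r1, r2])
    res = sasa(model, probe=probe, n_points=4000)
    exp1, exp2 = spherical_cap_pair_area(r1 + probe, r2 + probe, d)
    assert res.atom_area[0] == pytest.approx(exp1, rel=0.01)
    assert res.atom_area[1] == pytest.approx(exp2, rel=0.01)


def test_monte_carlo_oracle_on_random_clusters(rng):
    probe = 1.4
    for trial in range(3):
        n = int(rng.integers(5, 21))
        xyz = rng.uniform(-4.0, 4.0, size=(n, 3))
        radii = rng.uniform(1.2, 2.0, size=n)
        model = gen_sphere_cluster([tuple(p) for p in xyz], list(radii))
        res = sasa(model, probe=probe, n_points=2000)
        mc = monte_carlo_sasa(xyz, radii, probe, n_samples=40000, seed=trial)
        assert res.total_area == pytest.approx(mc.sum(), rel=0.02)


def test_agreement_with_biopython_shrake_rupley():
    """Independent-implementation cross-check on a random cluster."""
    from Bio.PDB.Atom import Atom
    from Bio.PDB.Chain import Chain
    from Bio.PDB.Model import Model
    from Bio.PDB.Residue import Residue
    from Bio.PDB.SASA import ShrakeRupley
    from Bio.PDB.Structure import Structure

    rng = np.random.default_rng(7)
    xyz = rng.uniform(-3.0, 3.0, size=(10, 3))
    radius = 1.7

    model = gen_sphere_cluster([tuple(p) for p in xyz], [radius] * 10)
    res = sasa(model, probe=1.4, n_points=960)

    structure = Structure("t")
    bio_model = Model(0)
    chain = Chain("A")
    for i, p in enumerate(xyz):
        residue = Residue((" ", i + 1, " "), "SPH", "")
        atom = Atom(f"C{i}", p, 0.0, 1.0, " ", f"C{i}", i + 1, element="C")
        residue.add(atom)
        chain.add(residue)
    bio_model.add(chain)
    structure.add(bio_model)
    sr = ShrakeRupley(probe_radius=1.4, n_points=960, radii_dict={"C": radius})
    sr.compute(structure, level="S")
    assert res.total_area == pytest.approx(structure.sasa, rel=0.02)


def test_rotation_translation_invariance(rng):
    xyz = rng.uniform(-3.0, 3.0, size=(8, 3))
    radii = rng.uniform(1.4, 1.9, size=8)
    model = gen_sphere_cluster([tuple(p) for p in xyz], list(radii))
    base = sasa(model, probe=1.4, n_points=2000).total_area
    # random rotation (QR) + translation
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    moved = xyz @ q.T + np.array([10.0, -5.0, 3.0])
    model2 = gen_sphere_cluster([tuple(p) for p in moved], list(radii))
    assert sasa(model2, probe=1.4, n_points=2000).total_area == pytest.approx(
        base, rel=0.01
    )


def test_adding_atoms_never_increases_existing_area(rng):
    xyz = rng.uniform(-2.0, 2.0, size=(5, 3))
    radii = [1.7] * 5
    model = gen_sphere_cluster([tuple(p) for p in xyz], radii)
    res5 = sasa(model, probe=1.4, n_points=960)
    xyz6 = np.vstack([xyz, [[0.5, 0.5, 0.5]]])
    model6 = gen_sphere_cluster([tuple(p) for p in xyz6], radii + [1.7])
    res6 = sasa(model6, probe=1.4, n_points=960)
    assert np.all(res6.atom_area[:5] <= res5.atom_area + 1e-9)


def test_npoints_convergence_cauchy():
    model = gen_sphere_cluster(
        [(0.0, 0.0, 0.0), (3.0, 0.0, 0.0), (0.0, 3.0, 0.0)], [1.8, 1.8, 1.8]
    )
    totals = [sasa(model, probe=1.4, n_points=n).total_area for n in (500, 2000, 8000)]
    assert abs(totals[2] - totals[1]) < abs(totals[1] - totals[0]) + 1e-6


def test_golden_spiral_points_on_unit_sphere():
    pts = golden_spiral_points(960)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
    # quasi-uniform: centroid near origin
    assert np.linalg.norm(pts.mean(axis=0)) < 0.01


def test_relative_accessibility_extremes():
    lone = gen_sphere_cluster([(0.0, 0.0, 0.0)], [1.8])
    res = sasa(lone, probe=5.0)
    assert relative_accessibility(res, "A", 1) == pytest.approx(100.0)


def test_sequon_accessibility_surface_vs_core():
    model = gen_globular_cluster(n_atoms=60, cluster_radius=8.0, seed=0)
    df = sequon_accessibility([model], [9001, 9002], probe=5.0, n_points=960)
    surf = df.set_index("position").loc[9001]
    core = df.set_index("position").loc[9002]
    assert surf["mean_rel_accessibility"] > 3 * max(core["mean_rel_accessibility"], 1.0)
    assert surf["class"] == "accessible"
    assert core["class"] == "occluded"


def test_sequon_accessibility_repeated_structure_sd_zero():
    model = gen_globular_cluster(seed=1)
    df = sequon_accessibility([model] * 5, [9001], probe=5.0, n_points=500)
    assert df.loc[0, "sd"] == pytest.approx(0.0, abs=1e-9)
    assert df.loc[0, "n_structures"] == 5


def test_sequon_accessibility_missing_position_raises():
    model = gen_globular_cluster(seed=1)
    with pytest.raises(KeyError):
        sequon_accessibility([model], [1234567])


def test_dimer_occlusion_far_apart_is_zero():
    mono = gen_globular_cluster(n_atoms=40, seed=2)
    dimer = gen_dimer(mono, separation=200.0)
    df = dimer_occlusion(mono, dimer, [("A", 9001, "ND2")], n_points=500)
    assert df.loc[0, "delta"] == pytest.approx(0.0, abs=1e-6)


def test_dimer_occlusion_identity():
    mono = gen_globular_cluster(n_atoms=30, seed=3)
    df = dimer_occlusion(mono, mono, [("A", 9001, "ND2")], n_points=500)
    assert df.loc[0, "delta"] == 0.0


def test_dimer_occlusion_interface_marker_loses_surface():
    # marker sits at +x on the surface; partner copy placed just beyond it
    mono = gen_globular_cluster(n_atoms=60, cluster_radius=8.0, seed=4)
    marker_x = 8.0 + 2.0 * 1.8
    dimer = gen_dimer(mono, separation=2.0 * marker_x + 1.0)
    df = dimer_occlusion(mono, dimer, [("A", 9001, "ND2")], probe=5.0, n_points=960)
    assert df.loc[0, "fractional_loss"] > 0.5


def test_dimer_occlusion_empty_selection_raises():
    mono = gen_globular_cluster(seed=5)
    with pytest.raises(ValueError):
        dimer_occlusion(mono, mono, [])


def test_pdb_roundtrip(tmp_path):
    model = gen_globular_cluster(n_atoms=20, seed=6)
    path = tmp_path / "toy.pdb"
    write_pdb(model, str(path))
    back = read_pdb(str(path))
    assert len(back) == len(model)
    assert np.allclose(back.xyz, model.xyz, atol=1e-3)
    assert list(back.element) == list(model.element)


def test_structure_validation():
    with pytest.raises(ValueError):
        StructureModel.from_atoms([])
    with pytest.raises(ValueError):
        gen_sphere_cluster([(np.nan, 0.0, 0.0)], [1.5])
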