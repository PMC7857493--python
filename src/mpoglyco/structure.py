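"""Solvent-accessible surface area and sequon accessibility.

Implements the Shrake–Rupley algorithm: each atom's sphere is expanded
by the probe radius and sampled with a deterministic golden-spiral
point lattice; the accessible fraction of points scales the expanded
sphere's area.  The probe defaults to 5 Å — a deliberately large probe
that reports on accessibility to bulky modifying enzymes rather than to
water — and points default to 960 per atom.

Van der Waals radii are element-based and ship as a text resource;
unknown elements fall back to 1.80 Å with a warning.  Hydrogens absent
from crystal structures are simply absent (united-atom convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "StructureModel",
    "AccessibilityResult",
    "load_radii_table",
    "golden_spiral_points",
    "sasa",
    "relative_accessibility",
    "sequon_accessibility",
    "dimer_occlusion",
    "read_pdb",
    "write_pdb",
]

DEFAULT_PROBE = 5.0
DEFAULT_N_POINTS = 960
FALLBACK_RADIUS = 1.80


def load_radii_table() -> dict[str, float]:
    """Element -> van der Waals radius (Å) from the shipped table."""
    text = resources.files("mpoglyco.data").joinpath("vdw_radii.tsv").read_text()
    table = {}
    for line in text.strip().splitlines()[1:]:
        element, radius = line.split("\t")
        table[element.upper()] = float(radius)
    return table


_RADII = load_radii_table()


@dataclass
class StructureModel:
    """Atoms with coordinates and radii; parallel numpy arrays."""

    serial: np.ndarray          # int
    element: np.ndarray         # str
    atom_name: np.ndarray       # str
    res_name: np.ndarray        # str
    res_seq: np.ndarray         # int
    chain_id: np.ndarray        # str
    xyz: np.ndarray             # (n, 3) float, Å
    radius: np.ndarray          # float, Å
    hetero: np.ndarray          # bool

    def __post_init__(self) -> None:
        n = len(self.serial)
        if n == 0:
            raise ValueError("structure has zero atoms")
        if self.xyz.shape != (n, 3) or not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates missing or non-finite")
        if np.any(self.radius <= 0):
            raise ValueError("non-positive van der Waals radius")

    def __len__(self) -> int:
        return len(self.serial)

    @classmethod
    def from_atoms(cls, atoms: list[dict]) -> "StructureModel":
        """Build from a list of atom dicts; radii looked up by element."""
        radii = []
        for a in atoms:
            el = a["element"].upper()
            if "radius" in a:
                radii.append(float(a["radius"]))
            elif el in _RADII:
                radii.append(_RADII[el])
            else:
                warnings.warn(f"no vdW radius for element {el!r}; using {FALLBACK_RADIUS} Å")
                radii.append(FALLBACK_RADIUS)
        return cls(
            serial=np.array([a.get("serial", i + 1) for i, a in enumerate(atoms)]),
            element=np.array([a["element"].upper() for a in atoms]),
            atom_name=np.array([a.get("name", a["element"]) for a in atoms]),
            res_name=np.array([a.get("res_name", "UNK") for a in atoms]),
            res_seq=np.array([a.get("res_seq", 1) for a in atoms]),
            chain_id=np.array([a.get("chain", "A") for a in atoms]),
            xyz=np.array([a["xyz"] for a in atoms], dtype=float),
            radius=np.array(radii, dtype=float),
            hetero=np.array([bool(a.get("hetero", False)) for a in atoms]),
        )

    def select(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(
            serial=self.serial[mask],
            element=self.element[mask],
            atom_name=self.atom_name[mask],
            res_name=self.res_name[mask],
            res_seq=self.res_seq[mask],
            chain_id=self.chain_id[mask],
            xyz=self.xyz[mask],
            radius=self.radius[mask],
            hetero=self.hetero[mask],
        )


@dataclass
class AccessibilityResult:
    """Per-atom and per-residue SASA for one structure."""

    atom_area: np.ndarray
    structure: StructureModel
    probe: float
    n_points: int

    @property
    def total_area(self) -> float:
        return float(self.atom_area.sum())

    def residue_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chain": self.structure.chain_id,
                "res_seq": self.structure.res_seq,
                "res_name": self.structure.res_name,
                "area": self.atom_area,
            }
        )
        return (
            df.groupby(["chain", "res_seq", "res_name"], sort=True)["area"]
            .sum()
            .reset_index()
        )

    def residue_area(self, chain: str, res_seq: int) -> float:
        mask = (self.structure.chain_id == chain) & (self.structure.res_seq == res_seq)
        if not mask.any():
            raise KeyError(f"residue {chain}/{res_seq} not in structure")
        return float(self.atom_area[mask].sum())


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-angle spiral)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def sasa(
    structure: StructureModel,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> AccessibilityResult:
    """Shrake–Rupley solvent-accessible surface area.

    For each atom, the fraction of ``n_points`` golden-spiral points on
    its probe-expanded sphere that fall outside every neighbour's
    expanded sphere, times 4*pi*(r + probe)^2.  Deterministic for a
    fixed lattice size.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    if probe < 0:
        raise ValueError("negative probe radius")
    unit = golden_spiral_points(n_points)
    expanded = structure.radius + probe
    tree = cKDTree(structure.xyz)
    areas = np.zeros(len(structure))
    for i in range(len(structure)):
        ri = expanded[i]
        neighbours = tree.query_ball_point(structure.xyz[i], ri + expanded.max())
        neighbours = [j for j in neighbours if j != i]
        pts = structure.xyz[i] + ri * unit
        if neighbours:
            centres = structure.xyz[neighbours]
            radii = expanded[neighbours]
            d2 = ((pts[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * math.pi * ri * ri
    return AccessibilityResult(atom_area=areas, structure=structure, probe=probe, n_points=n_points)


def relative_accessibility(
    result: AccessibilityResult,
    chain: str,
    res_seq: int,
    reference: float | None = None,
) -> float:
    """Percent accessibility of a residue relative to its fully exposed state.

    The reference is the same residue's atoms computed in isolation with
    the same probe, radii and point lattice (no neighbouring residues),
    i.e. a fully solvent-exposed copy; a caller-supplied reference area
    (e.g. from a tripeptide model) overrides it.
    """
    area = result.residue_area(chain, res_seq)
    if reference is None:
        mask = (result.structure.chain_id == chain) & (
            result.structure.res_seq == res_seq
        )
        isolated = sasa(
            result.structure.select(mask),
            probe=result.probe,
            n_points=result.n_points,
        )
        reference = isolated.total_area
    if reference <= 0:
        raise ValueError("non-positive reference area")
    return 100.0 * area / reference


def sequon_accessibility(
    structures: list[StructureModel],
    positions: list[int],
    chain: str = "A",
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    occluded_threshold: float = 25.0,
) -> pd.DataFrame:
    """Relative accessibility of sequon residues across structures.

    Returns one row per position with per-structure values, mean, SD and
    an occluded/accessible call at ``occluded_threshold`` percent.
    Positions missing from some structures are averaged over the
    structures that resolve them; a position missing everywhere raises.
    """
    per_pos: dict[int, list[float]] = {p: [] for p in positions}
    for model in structures:
        res = sasa(model, probe=probe, n_points=n_points)
        for p in positions:
            try:
                per_pos[p].append(relative_accessibility(res, chain, p))
            except KeyError:
                continue
    rows = []
    for p in positions:
        vals = per_pos[p]
        if not vals:
            raise KeyError(f"position {p} absent from all structures")
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            {
                "position": p,
                "n_structures": len(vals),
                "mean_rel_accessibility": mean,
                "sd": sd,
                "class": "occluded" if mean < occluded_threshold else "accessible",
            }
        )
    return pd.DataFrame(rows)


def dimer_occlusion(
    mono: StructureModel,
    dimer: StructureModel,
    target_atoms: list[tuple[str, int, str]],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> pd.DataFrame:
    """Per-target SASA loss upon assembly into the dimer.

    ``target_atoms`` lists (chain, res_seq, atom_name) triples that must
    exist in both models; the dimer SASA is evaluated within the full
    assembly.  The loss is reported signed.
    """
    if not target_atoms:
        raise ValueError("empty target-atom selection")
    res_mono = sasa(mono, probe=probe, n_points=n_points)
    res_dimer = sasa(dimer, probe=probe, n_points=n_points)
    rows = []
    for chain, res_seq, atom_name in target_atoms:
        a_mono = _atom_area(res_mono, chain, res_seq, atom_name)
        a_dim = _atom_area(res_dimer, chain, res_seq, atom_name)
        delta = a_mono - a_dim
        rows.append(
            {
                "chain": chain,
                "res_seq": res_seq,
                "atom": atom_name,
                "sasa_mono": a_mono,
                "sasa_dimer": a_dim,
                "delta": delta,
                "fractional_loss": delta / a_mono if a_mono > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _atom_area(result: AccessibilityResult, chain: str, res_seq: int, atom_name: str) -> float:
    s = result.structure
    mask = (s.chain_id == chain) & (s.res_seq == res_seq) & (s.atom_name == atom_name)
    if not mask.any():
        raise KeyError(f"atom {chain}/{res_seq}/{atom_name} not found")
    return float(result.atom_area[mask].sum())


def read_pdb(path: str, include_hetero: bool = True) -> StructureModel:
    """Read ATOM/HETATM records from a PDB file into a StructureModel."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    atoms = []
    model = st[0]
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            if het and not include_hetero:
                continue
            for atom in residue:
                atoms.append(
                    {
                        "serial": atom.serial,
                        "element": atom.element.name,
                        "name": atom.name,
                        "res_name": residue.name,
                        "res_seq": residue.seqid.num,
                        "chain": chain.name,
                        "xyz": (atom.pos.x, atom.pos.y, atom.pos.z),
                        "hetero": het,
                    }
                )
    return StructureModel.from_atoms(atoms)


def write_pdb(structure: StructureModel, path: str) -> None:
    """Write a StructureModel as minimal ATOM/HETATM records."""
    with open(path, "w") as fh:
        for i in range(len(structure)):
            record = "HETATM" if structure.hetero[i] else "ATOM  "
            x, y, z = structure.xyz[i]
            name = structure.atom_name[i][:4]
            fh.write(
                f"{record}{int(structure.serial[i]):5d} {name:<4s}"
                f"{structure.res_name[i][:3]:>4s} {structure.chain_id[i][:1]}"
                f"{int(structure.res_seq[i]):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {structure.element[i]:>2s}\n"
            )
        fh.write("END\n")
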