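"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated at desk scale:
glycopeptide AUC tables (Dirichlet site profiles with lognormal
measurement noise), native-MS traces (rendered envelopes plus baseline
noise), mass-photometry event lists (Gaussian mixtures), and toy
structures with analytically known surface areas.  All generators are
pure functions of (config, seed).

Defaults emulate the myeloperoxidase study conditions: five sequons
with 1-3 dominant glycoforms each (truncated species at Asn323/Asn483,
oligomannosidic at Asn355/Asn391, largely unoccupied Asn729), three
technical replicates, and a 7%/93% monoprotomer/diprotomer particle
mixture near 73 and 144 kDa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import MassEnvelope, ProteoformVariant, render_envelope
from .photometry import PhotometryEventSet
from .structure import StructureModel

__all__ = [
    "SimulationConfig",
    "gen_glycopeptide_table",
    "gen_native_spectrum",
    "gen_photometry_events",
    "gen_toy_structure",
    "gen_sphere_cluster",
    "gen_globular_cluster",
    "gen_dimer",
]

#: Per-site glycoform alphabets and Dirichlet concentrations mirroring the
#: sparsity of the measured site profiles (dominant species first).
DEFAULT_SITE_ALPHABETS: dict[int, dict[str, float]] = {
    323: {"M2F": 10.0, "M3F": 4.0, "M3": 1.0, "FA1": 1.0, "FA1G1S1a": 0.5},
    355: {"M6": 8.0, "M5": 6.0, "GlcNAc1": 1.0, "unoccupied": 0.5},
    391: {"M6": 8.0, "M5": 5.0, "GlcNAc1": 1.0, "unoccupied": 0.5},
    483: {"M3F": 8.0, "M2F": 4.0, "FA1": 2.0, "FA1G1": 1.0},
    729: {"unoccupied": 8.0, "GlcNAc1": 4.0, "GlcNAc1F": 2.0},
}


@dataclass
class SimulationConfig:
    """Ground-truth settings for all synthetic inputs."""

    seed: int = 0
    site_alphabets: dict[int, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SITE_ALPHABETS.items()}
    )
    true_profiles: dict[int, dict[str, float]] | None = None  # overrides Dirichlet draw
    n_replicates: int = 3
    auc_lognormal_sigma: float = 0.2
    site_intensity_mean: float = 1e6
    condition: str = "synthetic"
    envelope_fwhm: float = 250.0
    envelope_snr: float = 100.0
    photometry_means: tuple[float, ...] = (73.0, 144.0)
    photometry_sds: tuple[float, ...] = (6.0, 6.0)
    photometry_weights: tuple[float, ...] = (0.07, 0.93)
    photometry_n: int = 5000

    def __post_init__(self) -> None:
        if abs(sum(self.photometry_weights) - 1.0) > 1e-9:
            raise ValueError("photometry weights must sum to 1")
        if any(s <= 0 for s in self.photometry_sds):
            raise ValueError("photometry SDs must be positive")
        if self.auc_lognormal_sigma < 0:
            raise ValueError("negative lognormal sigma")


def gen_glycopeptide_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[int, dict[str, float]]]:
    """Simulate a long-format glycopeptide AUC table.

    Per site: a true profile (Dirichlet draw over the site alphabet, or
    the configured override), a lognormal site-level intensity scalar,
    and per-species lognormal noise in each replicate.  Returns the
    table and the ground-truth profiles.
    """
    rng = np.random.default_rng(config.seed)
    truth: dict[int, dict[str, float]] = {}
    rows = []
    for site, alphabet in sorted(config.site_alphabets.items()):
        codes = list(alphabet)
        if not codes:
            raise ValueError(f"empty glycoform alphabet for site {site}")
        if config.true_profiles is not None and site in config.true_profiles:
            profile = dict(config.true_profiles[site])
            total = sum(profile.values())
            profile = {c: v / total for c, v in profile.items()}
            codes = list(profile)
        else:
            alphas = np.array([alphabet[c] for c in codes])
            draw = rng.dirichlet(alphas)
            profile = dict(zip(codes, draw))
        truth[site] = profile
        scale = config.site_intensity_mean * rng.lognormal(0.0, 0.5)
        for rep in range(1, config.n_replicates + 1):
            for code in codes:
                noise = (
                    rng.lognormal(0.0, config.auc_lognormal_sigma)
                    if config.auc_lognormal_sigma > 0
                    else 1.0
                )
                rows.append(
                    {
                        "site": site,
                        "glycan": code,
                        "replicate": str(rep),
                        "condition": config.condition,
                        "auc": profile[code] * scale * noise,
                    }
                )
    return pd.DataFrame(rows), truth


def gen_native_spectrum(
    config: SimulationConfig,
    variants: list[ProteoformVariant],
) -> tuple[pd.DataFrame, MassEnvelope]:
    """Render an ensemble and add Gaussian baseline noise at the configured SNR."""
    envelope = render_envelope(variants, fwhm=config.envelope_fwhm)
    rng = np.random.default_rng(config.seed + 1)
    noise_sd = 1.0 / config.envelope_snr if config.envelope_snr > 0 else 0.0
    noisy = np.clip(
        envelope.intensity + rng.normal(0.0, noise_sd, len(envelope.intensity)),
        0.0,
        None,
    )
    df = pd.DataFrame({"mass": envelope.grid, "intensity": noisy})
    return df, envelope


def gen_photometry_events(config: SimulationConfig) -> PhotometryEventSet:
    """Draw single-particle masses from the configured Gaussian mixture."""
    if config.photometry_n <= 0:
        raise ValueError("photometry_n must be positive")
    rng = np.random.default_rng(config.seed + 2)
    comp = rng.choice(
        len(config.photometry_weights),
        size=config.photometry_n,
        p=config.photometry_weights,
    )
    means = np.asarray(config.photometry_means)[comp]
    sds = np.asarray(config.photometry_sds)[comp]
    masses = rng.normal(means, sds)
    masses = np.abs(masses)  # physical masses; negatives are vanishingly rare
    return PhotometryEventSet(masses=masses)


def gen_sphere_cluster(
    positions: list[tuple[float, float, float]],
    radii: list[float],
    element: str = "C",
) -> StructureModel:
    """Small atom cluster with analytically checkable surface area."""
    atoms = [
        {
            "serial": i + 1,
            "element": element,
            "name": f"{element}{i + 1}",
            "res_name": "SPH",
            "res_seq": i + 1,
            "chain": "A",
            "xyz": pos,
            "radius": r,
        }
        for i, (pos, r) in enumerate(zip(positions, radii))
    ]
    return StructureModel.from_atoms(atoms)


def gen_globular_cluster(
    n_atoms: int = 60,
    cluster_radius: float = 8.0,
    atom_radius: float = 1.8,
    seed: int = 0,
) -> StructureModel:
    """Pseudo-globular cluster with one surface and one core marker residue.

    The marker residues are single pseudo-asparagine atoms: ``SRF`` sits
    on the cluster surface (res_seq 9001), ``COR`` at the centre
    (res_seq 9002); the remaining atoms fill the ball quasi-uniformly.
    """
    rng = np.random.default_rng(seed)
    atoms = []
    # filler atoms quasi-uniform in the ball
    u = rng.uniform(size=(n_atoms, 3)) * 2.0 - 1.0
    norms = np.linalg.norm(u, axis=1)
    shell = rng.uniform(size=n_atoms) ** (1 / 3)
    pts = u / np.maximum(norms[:, None], 1e-9) * (shell * cluster_radius)[:, None]
    for i, p in enumerate(pts):
        atoms.append(
            {
                "serial": i + 1,
                "element": "C",
                "name": "C",
                "res_name": "FIL",
                "res_seq": i + 1,
                "chain": "A",
                "xyz": tuple(p),
                "radius": atom_radius,
            }
        )
    atoms.append(
        {
            "serial": n_atoms + 1,
            "element": "N",
            "name": "ND2",
            "res_name": "SRF",
            "res_seq": 9001,
            "chain": "A",
            "xyz": (cluster_radius + 2.0 * atom_radius, 0.0, 0.0),
            "radius": atom_radius,
        }
    )
    atoms.append(
        {
            "serial": n_atoms + 2,
            "element": "N",
            "name": "ND2",
            "res_name": "COR",
            "res_seq": 9002,
            "chain": "A",
            "xyz": (0.0, 0.0, 0.0),
            "radius": atom_radius,
        }
    )
    return StructureModel.from_atoms(atoms)


def gen_dimer(mono: StructureModel, separation: float) -> StructureModel:
    """Two copies of a structure translated apart along x (chains A and B)."""
    import copy

    atoms = []
    for model_idx, (chain, shift) in enumerate((("A", 0.0), ("B", separation))):
        for i in range(len(mono)):
            atoms.append(
                {
                    "serial": model_idx * len(mono) + i + 1,
                    "element": str(mono.element[i]),
                    "name": str(mono.atom_name[i]),
                    "res_name": str(mono.res_name[i]),
                    "res_seq": int(mono.res_seq[i]),
                    "chain": chain,
                    "xyz": (
                        float(mono.xyz[i, 0]) + shift,
                        float(mono.xyz[i, 1]),
                        float(mono.xyz[i, 2]),
                    ),
                    "radius": float(mono.radius[i]),
                }
            )
    return StructureModel.from_atoms(atoms)


def gen_toy_structure(kind: str = "globular", seed: int = 0, **kwargs) -> StructureModel:
    """Dispatch to the toy-structure builders by kind."""
    if kind == "globular":
        return gen_globular_cluster(seed=seed, **kwargs)
    if kind == "spheres":
        return gen_sphere_cluster(**kwargs)
    if kind == "dimer":
        mono = gen_globular_cluster(seed=seed, **{k: v for k, v in kwargs.items() if k != "separation"})
        return gen_dimer(mono, kwargs.get("separation", 50.0))
    raise ValueError(f"unknown toy-structure kind {kind!r}")
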