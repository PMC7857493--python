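"""Combinatorial glycoproteoform enumeration and native-MS envelope prediction.

A protomer glycoproteoform is one choice of glycoform per sequon plus
one level per modification factor (oxidation, truncation variants, ...).
Under the central simplifying assumption that sites and factors are
occupied independently, the weight of a variant is the product of its
per-site abundances and per-factor frequencies; diprotomers pair two
protomers drawn from the same weighted pool and are joined by the
interprotomer Cys-Cys bridge (two hydrogens lost).

Masses are on the average scale by default, appropriate for intact
assemblies near 144 kDa where isotopic fine structure is unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .glycans import UNOCCUPIED, glycan_mass, parse_shorthand
from .profiles import SiteGlycoprofile

__all__ = [
    "ProteoformVariant",
    "MassEnvelope",
    "VariantFactor",
    "enumerate_protomers",
    "pair_diprotomers",
    "render_envelope",
    "compare_envelopes",
]

H_MONO = 1.00783
H_AVG = 1.00794

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ProteoformVariant:
    """One fully specified glycoproteoform with its ensemble weight."""

    glycoforms: tuple[tuple[int, str], ...]   # (site, code) pairs
    factors: tuple[tuple[str, str], ...]      # (factor name, level id)
    mass: float
    weight: float

    def describe(self) -> str:
        sites = ",".join(f"N{s}:{g}" for s, g in self.glycoforms)
        facs = ",".join(f"{n}={l}" for n, l in self.factors)
        return f"[{sites}]" + (f"[{facs}]" if facs else "")


@dataclass(frozen=True)
class VariantFactor:
    """An independent categorical modification factor.

    ``levels`` maps a level id to (frequency, mass delta); frequencies
    must sum to 1.
    """

    name: str
    levels: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        total = sum(f for f, _ in self.levels.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"factor {self.name!r} frequencies sum to {total:.6g}")


@dataclass
class MassEnvelope:
    """A rendered theoretical mass spectrum on a uniform grid."""

    grid: np.ndarray        # Da, strictly increasing, uniform
    intensity: np.ndarray   # max-normalised
    fwhm: float

    @property
    def apex(self) -> float:
        """Apex mass; ties break toward lower mass (first argmax)."""
        return float(self.grid[int(np.argmax(self.intensity))])

    def span(self, frac: float = 0.01) -> tuple[float, float]:
        """Mass range where intensity exceeds ``frac`` of the maximum."""
        above = np.nonzero(self.intensity >= frac * self.intensity.max())[0]
        return float(self.grid[above[0]]), float(self.grid[above[-1]])


def enumerate_protomers(
    profiles: list[SiteGlycoprofile],
    base_mass: float,
    factors: list[VariantFactor] | None = None,
    theta: float = 1e-6,
    scale: str = "average",
) -> tuple[list[ProteoformVariant], float]:
    """Enumerate weighted protomer glycoproteoforms.

    Cartesian product over site profiles and variant factors with
    product weights; variants lighter than ``theta`` in weight are
    pruned.  Returns (variants, pruned_weight); retained + pruned
    weights sum to 1.
    """
    if not profiles:
        raise ValueError("no site profiles supplied")
    if not (0.0 <= theta < 1.0):
        raise ValueError("theta must be in [0, 1)")
    factors = factors or []
    site_choices = []
    for pr in profiles:
        choices = [
            (pr.site, code, ab, _conjugated_mass(code, scale))
            for code, ab in sorted(pr.abundances.items())
            if ab > 0
        ]
        if not choices:
            raise ValueError(f"site {pr.site} has an empty profile")
        site_choices.append(choices)
    factor_choices = [
        [(f.name, lvl, freq, delta) for lvl, (freq, delta) in sorted(f.levels.items()) if freq > 0]
        for f in factors
    ]

    variants: list[ProteoformVariant] = []
    pruned = 0.0
    for combo in product(*site_choices, *factor_choices):
        site_part = combo[: len(site_choices)]
        factor_part = combo[len(site_choices):]
        weight = 1.0
        mass = base_mass
        for _, _, ab, gmass in site_part:
            weight *= ab
            mass += gmass
        for _, _, freq, delta in factor_part:
            weight *= freq
            mass += delta
        if weight < theta:
            pruned += weight
            continue
        variants.append(
            ProteoformVariant(
                glycoforms=tuple((s, c) for s, c, _, _ in site_part),
                factors=tuple((n, l) for n, l, _, _ in factor_part),
                mass=mass,
                weight=weight,
            )
        )
    return variants, pruned


def _conjugated_mass(code: str, scale: str) -> float:
    if code == UNOCCUPIED:
        return 0.0
    return glycan_mass(parse_shorthand(code).composition, form="conjugated", scale=scale)


def pair_diprotomers(
    protomers: list[ProteoformVariant],
    theta: float = 0.0,
    scale: str = "average",
    renormalize: bool = False,
) -> tuple[list[ProteoformVariant], float]:
    """Pair protomers into diprotomers joined by the Cys-Cys bridge.

    Unordered pairs: weight 2*p_i*p_j for i != j and p_i^2 on the
    diagonal; mass is the protomer sum minus two hydrogens for the
    interprotomer disulfide.  Pruning at ``theta`` happens after pairing.
    """
    if not protomers:
        raise ValueError("empty protomer list")
    w = np.array([p.weight for p in protomers])
    if renormalize:
        w = w / w.sum()
    bridge = 2.0 * (H_MONO if scale == "monoisotopic" else H_AVG)
    out: list[ProteoformVariant] = []
    pruned = 0.0
    n = len(protomers)
    for i in range(n):
        for j in range(i, n):
            weight = w[i] * w[j] * (1.0 if i == j else 2.0)
            mass = protomers[i].mass + protomers[j].mass - bridge
            if weight < theta:
                pruned += weight
                continue
            out.append(
                ProteoformVariant(
                    glycoforms=protomers[i].glycoforms + protomers[j].glycoforms,
                    factors=protomers[i].factors + protomers[j].factors,
                    mass=mass,
                    weight=float(weight),
                )
            )
    return out, float(pruned)


def render_envelope(
    variants: list[ProteoformVariant],
    fwhm: float = 250.0,
    grid_spacing: float | None = None,
    pad_sigmas: float = 5.0,
) -> MassEnvelope:
    """Render a weighted variant ensemble as a sum of Gaussian peaks.

    Weights are binned onto a uniform grid and convolved with a
    Gaussian kernel of the requested FWHM (equivalent to summing one
    Gaussian per variant when the spacing is well below the FWHM).
    The result is max-normalised.
    """
    if not variants:
        raise ValueError("empty variant list")
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    sigma = fwhm * FWHM_TO_SIGMA
    if grid_spacing is None:
        grid_spacing = max(sigma / 12.0, 1e-6)
    masses = np.array([v.mass for v in variants])
    weights = np.array([v.weight for v in variants])
    lo = masses.min() - pad_sigmas * sigma
    hi = masses.max() + pad_sigmas * sigma
    n_bins = max(int(np.ceil((hi - lo) / grid_spacing)), 8)
    edges = lo + grid_spacing * np.arange(n_bins + 1)
    hist, _ = np.histogram(masses, bins=edges, weights=weights)
    intensity = gaussian_filter1d(hist, sigma / grid_spacing, mode="constant")
    if intensity.max() <= 0:
        raise ValueError("degenerate envelope")
    grid = 0.5 * (edges[:-1] + edges[1:])
    return MassEnvelope(grid=grid, intensity=intensity / intensity.max(), fwhm=fwhm)


def compare_envelopes(
    theoretical: MassEnvelope,
    observed_mass: np.ndarray,
    observed_intensity: np.ndarray,
) -> dict:
    """Compare a theoretical envelope with an observed mass/intensity trace.

    Reports the apex offset (theoretical - observed), the overlap
    coefficient (integral of the pointwise minimum of the two
    unit-area-normalised traces, in [0, 1]) and each trace's
    1-percent-of-maximum mass span.
    """
    observed_mass = np.asarray(observed_mass, float)
    observed_intensity = np.clip(np.asarray(observed_intensity, float), 0.0, None)
    order = np.argsort(observed_mass)
    observed_mass, observed_intensity = observed_mass[order], observed_intensity[order]

    apex_obs = float(observed_mass[int(np.argmax(observed_intensity))])
    apex_theo = theoretical.apex

    lo = max(theoretical.grid[0], observed_mass[0])
    hi = min(theoretical.grid[-1], observed_mass[-1])
    if lo >= hi:
        import warnings

        warnings.warn("envelope mass ranges are disjoint; overlap = 0")
        overlap = 0.0
    else:
        common = np.linspace(lo, hi, 4000)
        t = np.interp(common, theoretical.grid, theoretical.intensity, left=0, right=0)
        o = np.interp(common, observed_mass, observed_intensity, left=0, right=0)
        # unit-area normalisation over each trace's own full support
        t_area = np.trapezoid(theoretical.intensity, theoretical.grid)
        o_area = np.trapezoid(observed_intensity, observed_mass)
        overlap = float(np.trapezoid(np.minimum(t / t_area, o / o_area), common))

    obs_above = np.nonzero(observed_intensity >= 0.01 * observed_intensity.max())[0]
    return {
        "apex_theoretical": apex_theo,
        "apex_observed": apex_obs,
        "apex_offset": apex_theo - apex_obs,
        "overlap": overlap,
        "span_theoretical": theoretical.span(0.01),
        "span_observed": (
            float(observed_mass[obs_above[0]]),
            float(observed_mass[obs_above[-1]]),
        ),
    }
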