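"""Mass-photometry mixture analysis and apparent Kd.

Single-molecule mass photometry yields one mass per detected particle.
A K-component Gaussian mixture fitted by expectation-maximisation
reports species fractions (e.g. monoprotomer vs diprotomer); at a known
total particle concentration the monomer/dimer equilibrium gives an
apparent dissociation constant Kd = [M]^2 / [D].

The EM implementation is one-dimensional with quantile-spaced
initialisation and a variance floor of 1% of the component mean
(single-particle histograms have instrument-limited width, so a
collapsing component is a numerical artefact, not signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhotometryEventSet",
    "MixtureFit",
    "fit_mixture",
    "species_fractions",
    "kd_from_fractions",
]

SD_FLOOR_FRACTION = 0.01
_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class PhotometryEventSet:
    """Per-particle masses (kDa) with optional acquisition concentration."""

    masses: np.ndarray
    concentration_molar: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, float)
        object.__setattr__(self, "masses", m)
        if m.ndim != 1 or len(m) == 0:
            raise ValueError("need a non-empty 1-D mass list")
        if np.any(m <= 0) or not np.all(np.isfinite(m)):
            raise ValueError("particle masses must be positive and finite")


@dataclass
class MixtureFit:
    """Fitted K-component Gaussian mixture."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    ll_history: list[float]
    converged: bool
    n_iter: int

    @property
    def k(self) -> int:
        return len(self.means)


def _log_gauss(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    z = (x - mean) / sd
    return -0.5 * (z * z + _LOG_2PI) - np.log(sd)


def fit_mixture(
    events: PhotometryEventSet,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureFit:
    """Maximum-likelihood K-component Gaussian mixture via EM.

    Deterministic: means initialise at evenly spaced data quantiles,
    SDs at the pooled SD, weights uniform.  Convergence when the
    log-likelihood gain drops below ``tol``; non-convergence within
    ``max_iter`` returns the best fit flagged unconverged.
    """
    x = events.masses
    n = len(x)
    if k <= 0:
        raise ValueError("k must be positive")
    if n < 10 * k:
        raise ValueError(f"need >= {10 * k} events for k={k}, got {n}")

    q = (np.arange(k) + 0.5) / k
    means = np.quantile(x, q)
    pooled_sd = float(np.std(x))
    floor = np.maximum(SD_FLOOR_FRACTION * np.abs(means), 1e-12)
    sds = np.maximum(np.full(k, pooled_sd if pooled_sd > 0 else 1.0), floor)
    weights = np.full(k, 1.0 / k)

    ll_history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        log_p = np.stack(
            [np.log(weights[j]) + _log_gauss(x, means[j], sds[j]) for j in range(k)]
        )
        log_norm = np.logaddexp.reduce(log_p, axis=0)
        ll = float(log_norm.sum())
        resp = np.exp(log_p - log_norm)
        # M-step
        nk = resp.sum(axis=1)
        weights = nk / n
        means = (resp @ x) / nk
        var = (resp * (x[None, :] - means[:, None]) ** 2).sum(axis=1) / nk
        floor = np.maximum(SD_FLOOR_FRACTION * np.abs(means), 1e-12)
        sds = np.maximum(np.sqrt(var), floor)

        ll_history.append(ll)
        if len(ll_history) >= 2 and ll - ll_history[-2] < tol:
            converged = True
            break

    order = np.argsort(means)
    return MixtureFit(
        means=means[order],
        sds=sds[order],
        weights=weights[order],
        log_likelihood=ll_history[-1],
        ll_history=ll_history,
        converged=converged,
        n_iter=it,
    )


def species_fractions(
    fit: MixtureFit,
    expected_masses: dict[str, float],
    tolerance: float = 0.15,
) -> dict[str, float]:
    """Match mixture components to expected species masses.

    Each expected mass must match exactly one component within the
    fractional ``tolerance`` of the expected mass, and no component may
    absorb two species.  Matched weights are renormalised over the
    matched set.
    """
    matches: dict[str, int] = {}
    used: set[int] = set()
    for name, target in expected_masses.items():
        within = [
            j
            for j in range(fit.k)
            if abs(fit.means[j] - target) <= tolerance * target
        ]
        if not within:
            raise ValueError(f"no mixture component within {tolerance:.0%} of {name} ({target} kDa)")
        j = min(within, key=lambda j: abs(fit.means[j] - target))
        if j in used:
            raise ValueError(f"component {j} matched by two species (means {fit.means})")
        used.add(j)
        matches[name] = j
    total = sum(fit.weights[j] for j in matches.values())
    return {name: float(fit.weights[j] / total) for name, j in matches.items()}


def kd_from_fractions(f_mono: float, concentration_molar: float) -> float:
    """Apparent dissociation constant from the monomer particle fraction.

    With particle concentrations [M] = f*C and [D] = (1-f)*C,
    Kd = [M]^2/[D] = f^2 * C / (1 - f); units follow C.  Labelled
    apparent: it assumes equilibrium at the measured concentration.
    """
    if not (0.0 < f_mono < 1.0):
        raise ValueError("monomer fraction must be strictly between 0 and 1")
    if concentration_molar <= 0:
        raise ValueError("total particle concentration must be positive")
    return f_mono * f_mono * concentration_molar / (1.0 - f_mono)
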