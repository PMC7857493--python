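import numpy as np
import pytest

from mpoglyco.profiles import SiteGlycoprofile
from mpoglyco.proteins import load_mpo_record


@pytest.fixture(scope="session")
def mpo_record():
    return load_mpo_record()


@pytest.fixture
def simple_profile():
    return SiteGlycoprofile(site=323, abundances={"M2F": 0.5, "M3F": 0.3, "FA1": 0.2})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def spherical_cap_pair_area(r1: float, r2: float, d: float) -> tuple[float, float]:
    """Analytic accessible areas of two overlapping spheres (radii already
    probe-expanded, centres ``d`` apart).  Independent oracle for the
    Shrake-Rupley implementation."""
    a1 = 4.0 * np.pi * r1**2
    a2 = 4.0 * np.pi * r2**2
    if d >= r1 + r2:
        return a1, a2
    # distance from centre 1 to the intersection plane
    x1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    h1 = r1 - x1
    h2 = r2 - (d - x1)
    return a1 - 2.0 * np.pi * r1 * h1, a2 - 2.0 * np.pi * r2 * h2


def monte_carlo_sasa(xyz, radii, probe, n_samples, seed):
    """Monte-Carlo surface-sampling SASA oracle (random sphere points)."""
    rng = np.random.default_rng(seed)
    expanded = np.asarray(radii, float) + probe
    xyz = np.asarray(xyz, float)
    areas = np.zeros(len(xyz))
    for i in range(len(xyz)):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = xyz[i] + expanded[i] * v
        free = np.ones(n_samples, bool)
        for j in range(len(xyz)):
            if j == i:
                continue
            free &= ((pts - xyz[j]) ** 2).sum(axis=1) >= expanded[j] ** 2
        areas[i] = free.mean() * 4.0 * np.pi * expanded[i] ** 2
    return areas
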