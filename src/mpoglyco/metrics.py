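"""Glycan-processing metrics of the neutrophil truncation pathway.

Four per-site statistics summarise how far each site's glycans have
progressed through N-glycan processing and the exoglycosidase-driven
truncation pathway (FA1 -> M3F -> M2F and A1 -> M3 -> M2):

* oligomannose-to-processed conversion — share of occupied signal that
  has left the oligomannosidic state;
* core fucosylation — fucosylated share among FUT8-eligible glycans;
* beta-1,2-GlcNAc removal efficiency — hexosaminidase products over
  products + substrates still carrying terminal antenna GlcNAc;
* alpha-1,3-Man removal efficiency — within the paucimannosidic pool,
  Man1/Man2-type species over Man1/Man2/Man3-type species.

The exact numerator/denominator sets are this package's explicit
definitions, chosen so the biosynthetic substrate/product pairs of the
truncation pathway partition cleanly; galactosylated or sialylated
complex species are no longer hexosaminidase substrates and are
excluded from the GlcNAc-removal sets.  The unoccupied fraction is
excluded from every metric (occupancy is reported separately).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glycans import (
    UNOCCUPIED,
    GlycanClass,
    fut8_eligible,
    parse_shorthand,
)
from .profiles import SiteGlycoprofile, enrichment_test

__all__ = [
    "ProcessingMetrics",
    "oligomannose_conversion",
    "core_fucosylation",
    "glcnac_removal_efficiency",
    "man_removal_efficiency",
    "metrics_for_profile",
    "metrics_table",
    "accessibility_association",
]


@dataclass(frozen=True)
class ProcessingMetrics:
    site: int
    replicate: str
    condition: str
    oligomannose_conversion: float | None
    core_fucosylation: float | None
    glcnac_removal: float | None
    man_removal: float | None


def _occupied(profile: SiteGlycoprofile):
    for code, ab in profile.abundances.items():
        if code != UNOCCUPIED and ab > 0:
            yield parse_shorthand(code), ab


def _ratio(num: float, den: float) -> float | None:
    """num/den, or None when the denominator pool is empty (undefined)."""
    if den <= 0:
        return None
    return num / den


def oligomannose_conversion(profile: SiteGlycoprofile) -> float | None:
    """Occupied-signal share that is no longer oligomannosidic."""
    num = den = 0.0
    for g, ab in _occupied(profile):
        den += ab
        if g.glycan_class != GlycanClass.OLIGOMANNOSE:
            num += ab
    return _ratio(num, den)


def core_fucosylation(profile: SiteGlycoprofile) -> float | None:
    """Core-fucosylated share among FUT8-eligible (non-oligomannose) glycans."""
    num = den = 0.0
    for g, ab in _occupied(profile):
        if fut8_eligible(g):
            den += ab
            if g.core_fucosylated:
                num += ab
    return _ratio(num, den)


def glcnac_removal_efficiency(profile: SiteGlycoprofile) -> float | None:
    """Products / (products + substrates) for terminal beta-1,2-GlcNAc removal.

    Substrates: agalactosylated asialo complex species retaining terminal
    antenna GlcNAc.  Products: paucimannosidic and chitobiose core-type
    species.  Extended (Gal/NeuAc-capped) complex species are outside
    both sets.
    """
    products = substrates = 0.0
    for g, ab in _occupied(profile):
        if g.glycan_class in (GlycanClass.PAUCIMANNOSE, GlycanClass.CHITOBIOSE_CORE):
            products += ab
        elif g.has_b12_glcnac:
            substrates += ab
    return _ratio(products, products + substrates)


def man_removal_efficiency(profile: SiteGlycoprofile) -> float | None:
    """Within the paucimannosidic pool, the share trimmed past the Man3 core.

    Man1/Man2-type species (alpha-1,3-arm mannose removed) over the
    Man1/Man2/Man3-type pool; fucosylated and afucosylated species are
    pooled.  Man4 paucimannosidic species (if present) sit outside the
    alpha-1,3-arm question and are excluded.
    """
    num = den = 0.0
    for g, ab in _occupied(profile):
        if g.glycan_class == GlycanClass.PAUCIMANNOSE and g.composition.hex <= 3:
            den += ab
            if g.composition.hex <= 2:
                num += ab
    return _ratio(num, den)


def metrics_for_profile(profile: SiteGlycoprofile) -> ProcessingMetrics:
    return ProcessingMetrics(
        site=profile.site,
        replicate=profile.replicate,
        condition=profile.condition,
        oligomannose_conversion=oligomannose_conversion(profile),
        core_fucosylation=core_fucosylation(profile),
        glcnac_removal=glcnac_removal_efficiency(profile),
        man_removal=man_removal_efficiency(profile),
    )


def metrics_table(profiles: list[SiteGlycoprofile]) -> pd.DataFrame:
    """Per site x replicate x condition metric table (NaN where undefined)."""
    rows = []
    for pr in profiles:
        m = metrics_for_profile(pr)
        rows.append(
            {
                "site": m.site,
                "replicate": m.replicate,
                "condition": m.condition,
                "oligomannose_conversion": _nan(m.oligomannose_conversion),
                "core_fucosylation": _nan(m.core_fucosylation),
                "glcnac_removal": _nan(m.glcnac_removal),
                "man_removal": _nan(m.man_removal),
            }
        )
    return pd.DataFrame(rows)


def _nan(v: float | None) -> float:
    return math.nan if v is None else v


def accessibility_association(
    metric_values: dict[int, list[float]],
    accessibility: dict[int, float],
    occluded_sites: tuple[int, ...] = (355, 391),
    accessible_sites: tuple[int, ...] = (323, 483, 729),
) -> dict:
    """Compare each occluded site's metric replicates with pooled accessible ones.

    Returns group means +/- SD, per-occluded-site two-sample t-tests
    against the pooled accessible-site values, and the sign of the
    accessibility association (positive when accessible sites score
    higher).
    """
    for s in occluded_sites + accessible_sites:
        if s not in metric_values:
            raise KeyError(f"metric values missing for site {s}")
        if s not in accessibility:
            raise KeyError(f"accessibility missing for site {s}")
    pooled = [v for s in accessible_sites for v in metric_values[s]]
    if len(pooled) < 2:
        raise ValueError("need >= 2 pooled accessible replicates")
    out = {
        "accessible_mean": float(np.mean(pooled)),
        "accessible_sd": float(np.std(pooled, ddof=1)),
        "occluded": {},
    }
    occluded_all = [v for s in occluded_sites for v in metric_values[s]]
    diff = float(np.mean(pooled) - np.mean(occluded_all))
    out["association_sign"] = int(np.sign(diff))
    for s in occluded_sites:
        vals = metric_values[s]
        if len(vals) < 2:
            raise ValueError(f"site {s}: need >= 2 replicates")
        test = enrichment_test(pooled, vals)
        out["occluded"][s] = {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)),
            "accessibility": accessibility[s],
            **test,
        }
    return out
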