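"""Site-specific glycoform abundance profiles.

A profile maps glycoform shorthand codes (plus the reserved key
``unoccupied``) to relative abundances that sum to one within each
site x replicate, obtained by normalising extracted-ion-chromatogram
area-under-the-curve (AUC) values.  No ionisation-efficiency correction
is applied: occupancy is the AUC share of glycosylated peptide forms,
which is the convention of the quantitation this package models and a
documented source of bias.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .glycans import UNOCCUPIED, endoh_sensitive, parse_shorthand

__all__ = [
    "SiteGlycoprofile",
    "profile_from_auc_table",
    "profiles_from_auc_table",
    "occupancy",
    "endoh_transform",
    "profile_correlation",
    "enrichment_test",
    "aggregate_replicates",
]

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class SiteGlycoprofile:
    """Normalised glycoform abundances at one site in one replicate."""

    site: int
    abundances: dict[str, float]
    replicate: str = "1"
    condition: str = "nMPO"

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError(f"negative abundance at site {self.site}")
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"site {self.site} abundances sum to {total:.6g}, expected 1"
            )
        for code in self.abundances:
            if code != UNOCCUPIED:
                parse_shorthand(code)  # raises on invalid codes

    def abundance(self, code: str) -> float:
        return self.abundances.get(code, 0.0)

    def glycoforms(self) -> list[str]:
        return sorted(self.abundances)


def profile_from_auc_table(
    rows: list[tuple[int, str, str, float]], condition: str = "nMPO"
) -> list[SiteGlycoprofile]:
    """Build normalised profiles from (site, glycan, replicate, auc) rows."""
    df = pd.DataFrame(rows, columns=["site", "glycan", "replicate", "auc"])
    return profiles_from_auc_table(df, condition=condition)


def profiles_from_auc_table(df: pd.DataFrame, condition: str | None = None) -> list[SiteGlycoprofile]:
    """Build normalised profiles from a long-format AUC table.

    Expects columns site, glycan, replicate, auc and optionally condition.
    Within each site x replicate (x condition), abundance = auc / sum(auc).
    """
    df = df.copy()
    if (df["auc"] < 0).any():
        raise ValueError("negative AUC values")
    if "condition" not in df.columns:
        df["condition"] = condition if condition is not None else "nMPO"
    profiles = []
    for (site, rep, cond), grp in df.groupby(["site", "replicate", "condition"]):
        total = grp["auc"].sum()
        if total <= 0:
            raise ValueError(
                f"all-zero AUC for site {site} replicate {rep}: normalisation undefined"
            )
        ab = (grp.groupby("glycan")["auc"].sum() / total).to_dict()
        profiles.append(
            SiteGlycoprofile(
                site=int(site), abundances=ab, replicate=str(rep), condition=str(cond)
            )
        )
    return profiles


def occupancy(profile: SiteGlycoprofile) -> float:
    """Fraction of peptide signal carrying any glycan (1 - unoccupied share)."""
    return 1.0 - profile.abundance(UNOCCUPIED)


def endoh_transform(profile: SiteGlycoprofile) -> SiteGlycoprofile:
    """Simulate exhaustive endoglycosidase H treatment of one site.

    Every Endo H-sensitive glycoform collapses onto the single-GlcNAc
    stub ``GlcNAc1`` (a core-fucosylated sensitive species would map to
    ``GlcNAc1F``, though the sensitivity rule excludes fucosylated
    glycans); resistant species and the unoccupied fraction are
    untouched.  Idempotent and normalisation-conserving.
    """
    out: dict[str, float] = {}
    for code, ab in profile.abundances.items():
        if code == UNOCCUPIED:
            target = code
        else:
            g = parse_shorthand(code)
            if endoh_sensitive(g):
                target = "GlcNAc1F" if g.core_fucosylated else "GlcNAc1"
            else:
                target = code
        out[target] = out.get(target, 0.0) + ab
    return replace(profile, abundances=out)


def profile_correlation(p: SiteGlycoprofile, q: SiteGlycoprofile) -> float:
    """Pearson correlation of two profiles over the union of glycoform keys."""
    keys = sorted(set(p.abundances) | set(q.abundances))
    if len(keys) < 3:
        raise ValueError("need >= 3 glycoform keys for a profile correlation")
    x = np.array([p.abundance(k) for k in keys])
    y = np.array([q.abundance(k) for k in keys])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def enrichment_test(
    group_a: list[float],
    group_b: list[float],
    paired: bool = False,
    alternative: str = "two-sided",
) -> dict:
    """Student's t-test on per-replicate metric values between two groups.

    Returns mean difference (a - b), t statistic and p-value.  Identical
    degenerate groups (zero variance, zero difference) are reported with
    p = 1 and a flag rather than NaN.
    """
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    diff = float(a.mean() - b.mean())
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal group sizes")
        res = stats.ttest_rel(a, b, alternative=alternative)
    else:
        res = stats.ttest_ind(a, b, alternative=alternative)
    t, p = float(res.statistic), float(res.pvalue)
    degenerate = bool(np.isnan(t))
    if degenerate and diff == 0.0:
        t, p = 0.0, 1.0
    return {"difference": diff, "t": t, "p": p, "degenerate_variance": degenerate}


def aggregate_replicates(profiles: list[SiteGlycoprofile]) -> pd.DataFrame:
    """Mean +/- SD abundance per site x condition x glycoform across replicates."""
    rows = []
    for pr in profiles:
        for code, ab in pr.abundances.items():
            rows.append(
                {
                    "site": pr.site,
                    "condition": pr.condition,
                    "glycan": code,
                    "replicate": pr.replicate,
                    "abundance": ab,
                }
            )
    long = pd.DataFrame(rows)
    # absent species count as zero in a replicate's profile
    filled = (
        long.pivot_table(
            index=["site", "condition", "glycan"],
            columns="replicate",
            values="abundance",
            fill_value=0.0,
        )
        .stack()
        .rename("abundance")
        .reset_index()
    )
    agg = (
        filled.groupby(["site", "condition", "glycan"])["abundance"]
        .agg(mean="mean", sd="std")
        .reset_index()
    )
    agg["sd"] = agg["sd"].fillna(0.0)
    return agg
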