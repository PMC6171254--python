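"""Two-group comparison protocol for hemodynamic parameters.

Each aneurysm contributes one value per hemodynamic parameter (HP) at the
"more dangerous" site (the max-dE_m location on the intraoperative image)
and one at a "less dangerous" site.  Normality of each group is screened
with the Shapiro-Wilk test; if both groups pass at the gate alpha, the
groups are compared with a t test, otherwise with the Mann-Whitney U test.
Two-sided, independent-samples (Welch) by default; a paired variant
(paired t / Wilcoxon signed-rank) is available since the sites are paired
per aneurysm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fields import Weighting

__all__ = [
    "normality_gate",
    "compare_groups",
    "weight_sweep",
    "GroupComparisonResult",
    "HP_KINDS",
]

HP_KINDS = ("pressure", "wss", "osi", "wss_norm", "osi_norm", "chp")


@dataclass(frozen=True)
class GroupComparisonResult:
    hp_kind: str
    n: int
    mean_more: float
    sd_more: float
    mean_less: float
    sd_less: float
    test_used: str  # "t_test" | "mann_whitney_u"
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")
        if self.sd_more < 0 or self.sd_less < 0:
            raise ValueError("standard deviations must be >= 0")


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 3:
        raise ValueError(f"{name}: need at least 3 observations, got {arr.size}")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name}: non-finite values")
    return arr


def normality_gate(sample_a, sample_b, alpha: float = 0.05) -> str:
    """Choose the test: 't_test' if both groups pass Shapiro-Wilk, else
    'mann_whitney_u'.  A constant sample cannot be normal and fails the gate
    (unless alpha <= 0, which disables the gate entirely)."""
    a = _as_sample(sample_a, "sample_a")
    b = _as_sample(sample_b, "sample_b")
    if alpha <= 0:
        return "t_test"
    for s in (a, b):
        if np.ptp(s) == 0:
            return "mann_whitney_u"
        if sps.shapiro(s).pvalue < alpha:
            return "mann_whitney_u"
    return "t_test"


def _mannwhitney(more: np.ndarray, less: np.ndarray, paired: bool):
    if paired:
        return sps.wilcoxon(more, less, alternative="two-sided")
    # exact null distribution when both groups are small and untied
    pooled = np.concatenate([more, less])
    method = (
        "exact"
        if max(more.size, less.size) <= 8 and np.unique(pooled).size == pooled.size
        else "asymptotic"
    )
    return sps.mannwhitneyu(more, less, alternative="two-sided", method=method)


def compare_groups(
    more, less, hp_kind: str = "chp", alpha: float = 0.05, paired: bool = False
) -> GroupComparisonResult:
    """Mean +/- SD per group and the gate-selected two-sided test.

    ``more``/``less`` are per-case values at the more-/less-dangerous sites.
    SDs use the n-1 denominator.  Raises if both groups are constant and
    identical (no test is defined), or if paired groups differ in length.
    """
    m = _as_sample(more, "more")
    l = _as_sample(less, "less")
    if paired and m.size != l.size:
        raise ValueError("paired comparison needs equal group sizes")
    if np.ptp(m) == 0 and np.ptp(l) == 0 and m[0] == l[0]:
        raise ValueError("all values identical in both groups; comparison degenerate")

    test = normality_gate(m, l, alpha)
    if test == "t_test":
        res = sps.ttest_rel(m, l) if paired else sps.ttest_ind(m, l, equal_var=False)
    else:
        res = _mannwhitney(m, l, paired)
    return GroupComparisonResult(
        hp_kind=hp_kind,
        n=m.size,
        mean_more=float(m.mean()),
        sd_more=float(m.std(ddof=1)),
        mean_less=float(l.mean()),
        sd_less=float(l.std(ddof=1)),
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def weight_sweep(
    wssn_more,
    osin_more,
    wssn_less,
    osin_less,
    w1_grid: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    alpha: float = 0.05,
    paired: bool = False,
) -> pd.DataFrame:
    """Group comparison of per-case CHP across a grid of weighting factors.

    For each w1 the per-case CHP is w1*WSSnorm + (1-w1)*OSInorm at both
    sites, then the gate-selected test compares the groups.  The group mean
    columns are exactly affine in w1 by construction.
    """
    wm = _as_sample(wssn_more, "wssn_more")
    om = _as_sample(osin_more, "osin_more")
    wl = _as_sample(wssn_less, "wssn_less")
    ol = _as_sample(osin_less, "osin_less")
    if wm.size != om.size or wl.size != ol.size:
        raise ValueError("WSSnorm and OSInorm case counts differ")

    rows = []
    for w1 in sorted(float(w) for w in w1_grid):
        w = Weighting.from_w1(w1)  # validates the grid
        chp_more = w.w1 * wm + w.w2 * om
        chp_less = w.w1 * wl + w.w2 * ol
        res = compare_groups(chp_more, chp_less, "chp", alpha=alpha, paired=paired)
        rows.append(
            {
                "w1": w.w1,
                "w2": w.w2,
                "mean_more": res.mean_more,
                "sd_more": res.sd_more,
                "mean_less": res.mean_less,
                "sd_less": res.sd_less,
                "test_used": res.test_used,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)
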