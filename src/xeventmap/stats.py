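"""Method-agreement and group-comparison statistics.

Bland-Altman agreement between slice-selective and nonslice-selective GS
readings, two-way ANOVA (group x cumulative dose) with Bonferroni-corrected
per-dose contrasts for dose-response comparison, and plain two-sample
t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

LOA_MULTIPLIER = 1.96  # conventional 95% limits of agreement


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int
    scale: str
    differences: np.ndarray
    means: np.ndarray


def bland_altman(pairs: Sequence[Tuple[float, float]], scale: str = "percent_of_mean") -> BlandAltmanResult:
    """Bias and 95% limits of agreement for paired method readings.

    ``percent_of_mean`` expresses each difference as 100*(a-b)/((a+b)/2) —
    the % difference between the two methods; ``raw`` uses a-b directly.
    Limits of agreement are bias +/- 1.96 * sample SD of the differences.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (a, b) pairs")
    a, b = arr[:, 0], arr[:, 1]
    means = (a + b) / 2.0
    if scale == "raw":
        d = a - b
    elif scale == "percent_of_mean":
        if np.any(means == 0):
            raise ValueError("pair mean of zero on percent scale")
        d = 100.0 * (a - b) / means
    else:
        raise ValueError(f"unknown scale {scale!r}")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        n_pairs=len(d),
        scale=scale,
        differences=d,
        means=means,
    )


@dataclass
class DoseResponseComparison:
    groups: list
    doses: np.ndarray
    group_means: pd.DataFrame  # index dose, columns group
    group_sds: pd.DataFrame
    anova_table: pd.DataFrame  # type-II sums of squares
    contrasts: pd.DataFrame  # per-dose t, raw and Bonferroni-adjusted p
    alpha: float = 0.05

    @property
    def group_effect_p(self) -> float:
        return float(self.anova_table.loc["C(group)", "PR(>F)"])


def _tidy_from_curves(curves_by_group: Dict[str, Sequence[np.ndarray]], doses: Sequence[float]) -> pd.DataFrame:
    doses = np.asarray(doses, dtype=float)
    rows = []
    for group, curves in curves_by_group.items():
        for subj, gs in enumerate(curves):
            gs = np.asarray(gs, dtype=float)
            if gs.shape != doses.shape:
                raise ValueError(
                    f"group {group!r} subject {subj}: GS length {gs.shape} != dose grid {doses.shape}"
                )
            for d, v in zip(doses, gs):
                rows.append({"subject": f"{group}.{subj}", "group": group, "dose": d, "GS": v})
    return pd.DataFrame(rows)


def compare_dose_response(
    curves_by_group: Dict[str, Sequence[np.ndarray]],
    doses: Sequence[float],
    alpha: float = 0.05,
) -> DoseResponseComparison:
    """Two-way ANOVA (group x dose) on GS with Bonferroni per-dose contrasts.

    ``curves_by_group`` maps each group label to per-subject GS arrays on a
    common cumulative-dose grid. The ANOVA uses type-II sums of squares
    (robust to the mildly unbalanced designs typical here); per-dose group
    contrasts are Student t-tests with raw p multiplied by the number of
    dose levels (capped at 1).
    """
    if len(curves_by_group) < 2:
        raise ValueError("need at least two groups")
    tidy = _tidy_from_curves(curves_by_group, doses)
    doses = np.asarray(doses, dtype=float)

    model = smf.ols("GS ~ C(group) * C(dose)", data=tidy).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    groups = sorted(curves_by_group)
    rows = []
    n_levels = len(doses)
    for d in doses:
        sub = tidy[tidy["dose"] == d]
        a = sub.loc[sub["group"] == groups[0], "GS"].to_numpy()
        b = sub.loc[sub["group"] == groups[1], "GS"].to_numpy()
        t, p = two_sample_t(a, b)
        p_adj = min(1.0, p * n_levels)
        rows.append({"dose": d, "t": t, "p_raw": p, "p_bonferroni": p_adj,
                     "significant": p_adj < alpha})
    contrasts = pd.DataFrame(rows)

    means = tidy.pivot_table(index="dose", columns="group", values="GS", aggfunc="mean")
    sds = tidy.pivot_table(index="dose", columns="group", values="GS", aggfunc=lambda x: x.std(ddof=1))
    return DoseResponseComparison(
        groups=groups,
        doses=doses,
        group_means=means,
        group_sds=sds,
        anova_table=anova,
        contrasts=contrasts,
        alpha=alpha,
    )


def two_sample_t(
    group_a: Sequence[float], group_b: Sequence[float], flavor: str = "student"
) -> Tuple[float, float]:
    """Two-sided two-sample t-test; returns (t, p).

    ``student`` pools variances; ``welch`` does not. The degenerate case of
    zero variance in both groups with equal means returns (0, 1) by
    convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if flavor not in ("student", "welch"):
        raise ValueError(f"unknown t-test flavor {flavor!r}")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf if a.mean() > b.mean() else -np.inf), 0.0
    res = sps.ttest_ind(a, b, equal_var=(flavor == "student"))
    return float(res.statistic), float(res.pvalue)
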