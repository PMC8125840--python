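"""Per-feature two-group screening of the sensor-derived features.

Each of the 17 features is compared between the robust and pre-frail/frail
groups.  Normality is assessed per group with the Shapiro-Wilk test; when
both groups look normal the comparison is a classical one-way ANOVA (for two
groups, equivalent to the pooled t test with F = t^2), otherwise a two-sided
Mann-Whitney U test (exact when the smaller group has <= 8 subjects and there
are no ties, normal approximation with tie correction otherwise).  Features
with p < alpha form the candidate set for recursive feature elimination; no
multiplicity correction is applied by default, with Benjamini-Hochberg
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES

__all__ = [
    "TestResult",
    "normality_p",
    "route_and_test",
    "significant_features",
    "benjamini_hochberg",
]

#: Screening significance level.
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """Outcome of one feature's two-group comparison."""

    feature: str
    test: str  # "anova" | "mann_whitney"
    statistic: float
    p_value: float
    significant: bool
    alpha: float


def normality_p(values) -> float:
    """Shapiro-Wilk normality p-value of one sample (3 <= n <= 5000)."""
    x = np.asarray(values, float)
    if not 3 <= len(x) <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("normality test undefined for a constant sample")
    return float(sps.shapiro(x).pvalue)


def _mann_whitney(rg: np.ndarray, fg: np.ndarray) -> tuple[float, float]:
    has_ties = len(np.unique(np.concatenate([rg, fg]))) < len(rg) + len(fg)
    method = "exact" if (min(len(rg), len(fg)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(rg, fg, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def route_and_test(
    rg_values,
    fg_values,
    alpha: float = DEFAULT_ALPHA,
    feature: str = "",
    force: str | None = None,
) -> TestResult:
    """Compare one feature between groups, routing by per-group normality.

    Routes to one-way ANOVA when the Shapiro-Wilk p-value exceeds ``alpha``
    in BOTH groups, otherwise to the two-sided Mann-Whitney U test.  ``force``
    overrides the routing ("anova" or "mann_whitney").
    """
    rg = np.asarray(rg_values, float)
    fg = np.asarray(fg_values, float)
    if len(rg) < 3 or len(fg) < 3:
        raise ValueError("each group needs at least 3 observations")

    if force is not None:
        test = force
    else:
        try:
            normal = (normality_p(rg) > alpha) and (normality_p(fg) > alpha)
        except ValueError:  # constant sample: clearly non-normal
            normal = False
        test = "anova" if normal else "mann_whitney"

    if test == "anova":
        stat, p = sps.f_oneway(rg, fg)
    elif test == "mann_whitney":
        stat, p = _mann_whitney(rg, fg)
    else:
        raise ValueError(f"unknown test {test!r}")
    return TestResult(
        feature=feature,
        test=test,
        statistic=float(stat),
        p_value=float(p),
        significant=bool(p < alpha),
        alpha=alpha,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def significant_features(
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    correction: str | None = None,
) -> tuple[list[str], list[TestResult]]:
    """Screen all 17 features; return the significant ones in canonical order.

    ``correction="bh"`` applies Benjamini-Hochberg to the routed p-values
    before thresholding (off by default, matching the reference analysis).
    """
    if "status" not in table.columns:
        raise ValueError("table must have a 'status' column")
    status = table["status"].to_numpy()
    if not set(np.unique(status)) <= {0, 1}:
        raise ValueError("status must be binary 0/1")
    rg_mask, fg_mask = status == 0, status == 1

    results = [
        route_and_test(
            table.loc[rg_mask, name], table.loc[fg_mask, name], alpha, feature=name
        )
        for name in FEATURE_NAMES
        if name in table.columns
    ]
    if correction == "bh":
        adj = benjamini_hochberg([r.p_value for r in results])
        results = [
            TestResult(r.feature, r.test, r.statistic, float(q), bool(q < alpha), alpha)
            for r, q in zip(results, adj)
        ]
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    selected = [r.feature for r in results if r.significant]
    return selected, results
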