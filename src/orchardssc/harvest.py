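"""Destructive vs non-destructive SSC agreement at harvest.

Compares laboratory refractometer values against spectral-model SSC on
independent harvest samples: per-method means and spreads, per-treatment-
level mean differences, and the Mann-Whitney-Wilcoxon rank-sum test (the
modelled SSC values are generally not normally distributed, so a rank test
is used instead of a t-test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["mann_whitney", "method_difference", "MethodComparison"]


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test; returns (U of ``a``, p-value).

    Small samples (both sides <= 20) without ties use the exact null
    distribution; otherwise the normal approximation with midrank tie
    correction and continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= 20 and b.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class MethodComparison:
    """Summary of destructive vs non-destructive agreement."""

    method_means: dict[str, float]
    method_sds: dict[str, float]
    level_differences: pd.DataFrame  # treatment_level, destructive, nondestructive, diff
    mean_abs_difference: float
    mean_signed_difference: float
    n_excluded_levels: int
    u_statistic: float
    p_value: float


def method_difference(samples: pd.DataFrame) -> MethodComparison:
    """Per-level mean differences between the two methods plus the rank test.

    ``samples`` needs columns ``method`` (``destructive`` /
    ``nondestructive``), ``treatment_level`` and ``ssc``.  Treatment levels
    observed under only one method are excluded (counted, not raised).  The
    headline number is the grand mean of the per-level absolute differences
    |destructive - nondestructive|; the signed mean is reported alongside as
    a bias check.
    """
    for col in ("method", "treatment_level", "ssc"):
        if col not in samples.columns:
            raise ValueError(f"missing column {col!r}")
    methods = set(samples["method"].unique())
    if not {"destructive", "nondestructive"} <= methods:
        raise ValueError("need both destructive and nondestructive samples")

    method_means = samples.groupby("method")["ssc"].mean().to_dict()
    method_sds = samples.groupby("method")["ssc"].std(ddof=1).to_dict()

    level_means = (
        samples.pivot_table(index="treatment_level", columns="method", values="ssc")
    )
    complete = level_means.dropna(subset=["destructive", "nondestructive"])
    n_excluded = len(level_means) - len(complete)
    diffs = complete["destructive"] - complete["nondestructive"]
    table = complete.reset_index()
    table["difference"] = diffs.to_numpy()

    u, p = mann_whitney(
        samples.loc[samples["method"] == "destructive", "ssc"].to_numpy(),
        samples.loc[samples["method"] == "nondestructive", "ssc"].to_numpy(),
    )
    return MethodComparison(
        method_means={k: float(v) for k, v in method_means.items()},
        method_sds={k: float(v) for k, v in method_sds.items()},
        level_differences=table,
        mean_abs_difference=float(diffs.abs().mean()),
        mean_signed_difference=float(diffs.mean()),
        n_excluded_levels=int(n_excluded),
        u_statistic=u,
        p_value=p,
    )
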