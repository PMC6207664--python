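"""Group-level statistics for the two-platform threshold study.

All analyses operate on log10 thresholds: the suppression index is a
difference of log10 thresholds, cross-platform agreement is a Pearson
correlation of log thresholds, the 2x2 (size x platform)
repeated-measures ANOVA decomposes log thresholds, and central tendencies
are geometric means with t-based confidence intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, IncompleteDesignError
from .fitting import TestResult

__all__ = [
    "suppression_index",
    "pearson_correlation",
    "rm_anova_2x2",
    "paired_t_test",
    "geometric_mean_ci",
]


def suppression_index(thr_small: float, thr_large: float) -> float:
    """log10(threshold_large) - log10(threshold_small).

    Positive when the large grating needs a longer duration, i.e. when
    motion discrimination worsens with size (surround suppression).
    Invariant to a common rescaling of both thresholds.
    """
    if thr_small <= 0 or thr_large <= 0:
        raise ValueError("thresholds must be positive")
    return float(np.log10(thr_large) - np.log10(thr_small))


def pearson_correlation(x, y, alpha: float = 0.05) -> TestResult:
    """Pearson correlation with the two-sided t-based p-value (df = n - 2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("zero variance in correlation input")
    r, p = stats.pearsonr(x, y)
    return TestResult(
        statistic=float(r),
        df=len(x) - 2,
        p_value=float(p),
        significant=p < alpha,
        alpha=alpha,
        name="pearson",
    )


def paired_t_test(x, y, alpha: float = 0.05) -> TestResult:
    """Two-sided paired t test, df = n - 1."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("x and y must have equal length >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            return TestResult(0.0, len(d) - 1, 1.0, False, alpha, name="paired_t")
        raise DegenerateDataError("zero variance of differences")
    t, p = stats.ttest_rel(x, y)
    return TestResult(
        statistic=float(t),
        df=len(x) - 1,
        p_value=float(p),
        significant=p < alpha,
        alpha=alpha,
        name="paired_t",
    )


def _paired_f(contrast: np.ndarray, alpha: float, name: str) -> TestResult:
    """F test (df 1, n-1) of a within-participant contrast against zero.

    For two-level within-subject factors the ANOVA F is exactly the
    square of the paired t on the per-participant contrast.
    """
    n = len(contrast)
    sd = np.std(contrast, ddof=1)
    if sd == 0:
        if np.mean(contrast) == 0:
            return TestResult(0.0, (1, n - 1), 1.0, False, alpha, name=name)
        raise DegenerateDataError(f"zero contrast variance for effect {name}")
    t = np.mean(contrast) / (sd / np.sqrt(n))
    F = t**2
    p = float(stats.f.sf(F, 1, n - 1))
    return TestResult(
        statistic=float(F),
        df=(1, n - 1),
        p_value=p,
        significant=p < alpha,
        alpha=alpha,
        name=name,
    )


def rm_anova_2x2(
    table: pd.DataFrame, alpha: float = 0.05
) -> dict[str, TestResult]:
    """Two-way (size x platform) repeated-measures ANOVA on a long table.

    ``table`` needs columns ``participant``, ``size``, ``platform`` and
    ``value`` (log10 threshold), with all four cells present for every
    participant.  Returns F tests for the size and platform main effects
    and the interaction, each with df (1, n_participants - 1).  Within-
    subject centering is implicit: each F depends only on within-
    participant contrasts, so adding a per-participant constant to all
    four cells changes nothing.
    """
    required = {"participant", "size", "platform", "value"}
    missing = required - set(table.columns)
    if missing:
        raise IncompleteDesignError(f"table is missing columns: {sorted(missing)}")
    wide = table.pivot_table(
        index="participant", columns=["size", "platform"], values="value"
    )
    sizes = sorted(table["size"].unique())
    platforms = sorted(table["platform"].unique())
    if len(sizes) != 2 or len(platforms) != 2:
        raise IncompleteDesignError("design must have exactly 2 sizes x 2 platforms")
    if wide.isna().any().any() or wide.shape[1] != 4:
        raise IncompleteDesignError("every participant needs all 4 cells")
    if len(wide) < 2:
        raise IncompleteDesignError("need at least 2 participants")
    c = {
        (s, p): wide[(s, p)].to_numpy() for s in sizes for p in platforms
    }
    s0, s1 = sizes
    p0, p1 = platforms
    size_contrast = (c[(s1, p0)] + c[(s1, p1)]) / 2 - (c[(s0, p0)] + c[(s0, p1)]) / 2
    plat_contrast = (c[(s0, p1)] + c[(s1, p1)]) / 2 - (c[(s0, p0)] + c[(s1, p0)]) / 2
    inter_contrast = (c[(s1, p1)] - c[(s0, p1)]) - (c[(s1, p0)] - c[(s0, p0)])
    return {
        "size": _paired_f(size_contrast, alpha, "anova_size"),
        "platform": _paired_f(plat_contrast, alpha, "anova_platform"),
        "interaction": _paired_f(inter_contrast / 2.0, alpha, "anova_interaction"),
    }


def geometric_mean_ci(values, level: float = 0.99):
    """Geometric mean with a t-based CI computed in the log10 domain.

    Returns ``(gmean, (lo, hi))`` in the original units (s).
    """
    v = np.asarray(values, float)
    if np.any(v <= 0):
        raise ValueError("all values must be positive")
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    logs = np.log10(v)
    m = logs.mean()
    se = logs.std(ddof=1) / np.sqrt(len(v))
    tcrit = stats.t.ppf(1.0 - (1.0 - level) / 2.0, len(v) - 1)
    return float(10.0**m), (float(10.0 ** (m - tcrit * se)), float(10.0 ** (m + tcrit * se)))
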