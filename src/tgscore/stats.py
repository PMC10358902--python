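"""Group-comparison statistics and standardized effect sizes.

Every comparison is gated on parametric assumptions: Shapiro-Wilk normality
per group and Levene homogeneity of variance, both at alpha 0.05.  When the
gate passes, the parametric test runs (independent t, repeated-measures
ANOVA, one-sample t); otherwise the rank-based equivalent (Mann-Whitney U
with exact small-sample p-values, Friedman, Wilcoxon signed-rank).

The standardized mean difference for a within-group change is Cohen's d
computed as the mean change divided by the group's baseline standard
deviation — the "baseline SD" standardizer, appropriate when training may
itself alter the spread.  Thresholds: trivial < 0.20, small 0.20-0.49,
medium 0.50-0.79, large >= 0.80.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

EffectLabel = Literal["trivial", "small", "medium", "large"]
TestName = Literal["t", "mann-whitney", "wilcoxon", "rm-anova", "friedman", "one-sample-t"]


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d with qualitative label and 95% CI of the mean difference."""

    d: float
    label: EffectLabel
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class TestDecision:
    """A gated test: which test ran, why, and what it found."""

    chosen_test: TestName
    statistic: float
    p_value: float
    shapiro_p: float = float("nan")
    levene_p: float = float("nan")
    n: int = 0


def effect_label(d: float) -> EffectLabel:
    """Qualitative Cohen's d label; a monotone step function of |d|."""
    a = abs(d)
    if a < 0.20:
        return "trivial"
    if a < 0.50:
        return "small"
    if a < 0.80:
        return "medium"
    return "large"


def cohens_d_change(
    mean_change: float,
    baseline_sd: float,
    n: int | None = None,
    change_sd: float | None = None,
) -> EffectSize:
    """Standardized mean difference of a within-group change.

    d = mean change / baseline SD (reported to full precision; round to two
    decimals for tabulation).  When ``n`` and ``change_sd`` are given, the
    95% CI of the *mean change* (t-based) is attached; otherwise the CI is
    NaN.
    """
    if baseline_sd <= 0:
        raise ValueError(f"baseline SD must be positive, got {baseline_sd}")
    d = mean_change / baseline_sd
    if n is not None and change_sd is not None and n > 1:
        se = change_sd / np.sqrt(n)
        tcrit = stats.t.ppf(0.975, n - 1)
        lo, hi = mean_change - tcrit * se, mean_change + tcrit * se
    else:
        lo = hi = float("nan")
    return EffectSize(d=d, label=effect_label(d), ci_low=lo, ci_high=hi)


def percent_difference(a: float, b: float) -> float:
    """How much larger ``a`` is than ``b``, as a percentage of ``b``."""
    if b == 0:
        raise ValueError("reference value is zero")
    return 100.0 * (a - b) / b


def random_hit_probability(alpha: float, n_hits: int, panel_size: int | None = None) -> float:
    """Chance of one gene being flagged ``n_hits`` times independently at level alpha.

    The probability of the same gene clearing an alpha-level screen ``n_hits``
    times by chance alone is alpha**n_hits; scaled by ``panel_size`` it gives
    the expected number of such repeat-hit genes across the screened panel.
    Used to argue that repeat hits on one gene are unlikely to be type I
    errors.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    if n_hits < 1:
        raise ValueError("n_hits must be >= 1")
    p = alpha**n_hits
    return p * panel_size if panel_size is not None else p


def parametric_gate(*samples: Sequence[float], alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk (worst group) and Levene p-values, and whether both pass.

    Samples with fewer than 3 observations or zero variance force the
    nonparametric branch with a warning.
    """
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(len(a) < 3 for a in arrays):
        warnings.warn("sample with n < 3: nonparametric test forced", stacklevel=2)
        return float("nan"), float("nan"), False
    if any(np.ptp(a) == 0 for a in arrays):
        warnings.warn("constant sample: nonparametric test forced", stacklevel=2)
        return float("nan"), float("nan"), False
    shapiro_p = min(float(stats.shapiro(a).pvalue) for a in arrays)
    if len(arrays) >= 2:
        levene_p = float(stats.levene(*arrays, center="mean").pvalue)
    else:
        levene_p = float("nan")
    passes = shapiro_p > alpha and (np.isnan(levene_p) or levene_p > alpha)
    return shapiro_p, levene_p, passes


def compare_groups(
    eg_values: Sequence[float],
    cg_values: Sequence[float],
    paired: bool = False,
) -> TestDecision:
    """Two-group comparison with the parametric gate.

    Unpaired: independent t-test, or Mann-Whitney U (exact p for n <= 20 per
    group, normal approximation above).  Paired: paired t or Wilcoxon
    signed-rank.
    """
    x = np.asarray(eg_values, dtype=float)
    y = np.asarray(cg_values, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    shapiro_p, levene_p, ok = parametric_gate(x, y)
    n = len(x) + len(y)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired comparison needs equal-length samples")
        if ok:
            res = stats.ttest_rel(x, y)
            return TestDecision("t", float(res.statistic), float(res.pvalue), shapiro_p, levene_p, n)
        res = stats.wilcoxon(x, y)
        return TestDecision("wilcoxon", float(res.statistic), float(res.pvalue), shapiro_p, levene_p, n)
    if ok:
        res = stats.ttest_ind(x, y)
        return TestDecision("t", float(res.statistic), float(res.pvalue), shapiro_p, levene_p, n)
    method = "exact" if max(len(x), len(y)) <= 20 and not _has_ties(x, y) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestDecision("mann-whitney", float(res.statistic), float(res.pvalue), shapiro_p, levene_p, n)


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    combined = np.concatenate([x, y])
    return len(np.unique(combined)) < len(combined)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """U and U' statistics (U + U' = n1*n2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u1 = float(stats.mannwhitneyu(x, y, alternative="two-sided").statistic)
    return min(u1, len(x) * len(y) - u1), max(u1, len(x) * len(y) - u1)


def within_group_course(
    week0: Sequence[float],
    week4: Sequence[float],
    week8: Sequence[float],
) -> TestDecision:
    """Repeated-measures ANOVA (Friedman fallback) across the three test weeks.

    Rows are participants; incomplete cases (NaN anywhere) are dropped with
    a warning.  Identical columns give F = 0, p = 1.
    """
    mat = np.column_stack([
        np.asarray(week0, dtype=float),
        np.asarray(week4, dtype=float),
        np.asarray(week8, dtype=float),
    ])
    complete = ~np.isnan(mat).any(axis=1)
    if not complete.all():
        warnings.warn(f"{(~complete).sum()} incomplete case(s) dropped", stacklevel=2)
    mat = mat[complete]
    n = mat.shape[0]
    if n < 3:
        raise ValueError(f"need >=3 complete cases, got {n}")
    if np.allclose(mat, mat[:, [0]]):
        return TestDecision("rm-anova", 0.0, 1.0, n=n)
    diffs = mat - mat.mean(axis=1, keepdims=True)
    shapiro_p, levene_p, ok = parametric_gate(*(diffs[:, j] for j in range(3)))
    if ok:
        stat, p = _rm_anova(mat)
        return TestDecision("rm-anova", stat, p, shapiro_p, levene_p, n)
    res = stats.friedmanchisquare(mat[:, 0], mat[:, 1], mat[:, 2])
    return TestDecision("friedman", float(res.statistic), float(res.pvalue), shapiro_p, levene_p, n)


def _rm_anova(mat: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA from the subject x condition matrix."""
    n, k = mat.shape
    grand = mat.mean()
    ss_cond = n * ((mat.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((mat.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((mat - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond, df_err = k - 1, (k - 1) * (n - 1)
    if ss_err <= 0:
        return float("inf"), 0.0
    f = (ss_cond / df_cond) / (ss_err / df_err)
    p = float(stats.f.sf(f, df_cond, df_err))
    return float(f), p


def heterogeneity_test(changes: Sequence[float]) -> tuple[TestDecision, tuple[float, float]]:
    """One-sample t of the percent changes against zero, with 95% CI.

    A significant result means participants' responses are heterogeneous in
    sign/magnitude relative to no change.  Zero variance is degenerate.
    """
    x = np.asarray(changes, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need >=3 observations, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: one-sample t undefined")
    res = stats.ttest_1samp(x, 0.0)
    ci = res.confidence_interval(0.95)
    return (
        TestDecision("one-sample-t", float(res.statistic), float(res.pvalue), n=len(x)),
        (float(ci.low), float(ci.high)),
    )
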