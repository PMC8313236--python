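"""Standardised effect sizes for relatedness--disease meta-analysis.

Two effect sizes are supported:

* ``Zr`` — the Fisher z-transform of a Pearson correlation ``r`` between
  within-group relatedness and an outcome (mortality rate or pathogen
  abundance), with sampling variance ``1/(n - 3)`` where ``n`` is the
  number of groups contributing to the correlation.
* ``LnCVR`` — the log ratio of coefficients of variation between
  high- and low-relatedness arms, a standardised effect size for
  differences in *across-group variability* that accounts for
  mean–variance coupling.

Primary studies report their results in many shapes (test statistics,
group means with dispersions, correlations).  The converters here turn
each of those into ``r`` (and from there into ``Zr``), following the
standard meta-analytic conversion formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupSummary",
    "ReportedStatistic",
    "r_from_statistic",
    "r_from_group_means",
    "fisher_z",
    "resample_r_from_summaries",
    "lncvr",
    "lncvr_variance",
    "log_mean_sd_correlation",
    "sd_from_dispersion",
    "reverse_survival_signs",
]


@dataclass(frozen=True)
class GroupSummary:
    """Across-group mean/SD of an outcome for one relatedness arm.

    ``mean`` and ``sd`` summarise the outcome (mortality proportion or
    pathogen count) *across groups* — not across individuals within a
    group — and ``n_groups`` is the number of groups in the arm.
    ``relatedness_level`` is ``"low"``/``"high"`` for two-arm designs or
    a mean relatedness value for continuous designs.
    """

    mean: float
    sd: float
    n_groups: int
    relatedness_level: str | float = "low"

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValueError("group mean must be finite")
        if self.sd < 0:
            raise ValueError("group sd must be non-negative")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")


@dataclass(frozen=True)
class ReportedStatistic:
    """A test statistic reported by a primary study.

    ``stat_type`` is one of ``t``, ``F_1df`` (F with one numerator df),
    ``chi2_1df``, or ``correlation_r``.  ``df_or_n`` is the error df for
    t/F and the total number of groups for chi-square.  ``direction_sign``
    carries the direction of the underlying association, which the
    statistic itself (F, chi-square) may not encode.
    """

    stat_type: str
    value: float
    df_or_n: float
    direction_sign: int = 1

    def __post_init__(self) -> None:
        if self.stat_type not in {"t", "F_1df", "chi2_1df", "correlation_r"}:
            raise ValueError(f"unsupported stat_type: {self.stat_type!r}")
        if not math.isfinite(self.value):
            raise ValueError("statistic value must be finite")
        if self.direction_sign not in (-1, 1):
            raise ValueError("direction_sign must be +1 or -1")
        if self.stat_type == "correlation_r" and abs(self.value) > 1:
            raise ValueError("|r| cannot exceed 1")


def r_from_statistic(stat: ReportedStatistic) -> float:
    """Convert a reported test statistic to a Pearson correlation.

    Uses the canonical meta-analytic conversions:
    ``t -> sqrt(t^2 / (t^2 + df))``; F with one numerator df is treated
    as ``t = sqrt(F)``; ``chi2(1 df) -> sqrt(chi2 / N)``; a reported
    correlation passes through.  The sign comes from ``direction_sign``
    (for t, the statistic's own sign is folded into the magnitude first).
    """
    s = stat
    if s.stat_type == "correlation_r":
        return s.direction_sign * abs(s.value)
    if s.df_or_n <= 0:
        raise ValueError("df_or_n must be positive")
    if s.stat_type == "t":
        t2 = s.value**2
        r = math.sqrt(t2 / (t2 + s.df_or_n))
    elif s.stat_type == "F_1df":
        if s.value < 0:
            raise ValueError("F statistic cannot be negative")
        t2 = s.value
        r = math.sqrt(t2 / (t2 + s.df_or_n))
    else:  # chi2_1df
        if s.value < 0:
            raise ValueError("chi-square statistic cannot be negative")
        r = math.sqrt(s.value / s.df_or_n)
    if r > 1:
        raise ValueError(
            f"conversion produced |r| = {r:.4f} > 1; inputs are inconsistent"
        )
    return s.direction_sign * r


def r_from_group_means(low: GroupSummary, high: GroupSummary) -> float:
    """Point-biserial ``r`` from high- vs low-relatedness arm summaries.

    The standardised mean difference ``d`` (pooled SD) is converted to
    ``r`` with the unequal-n correction ``a = (n_L + n_H)^2 / (n_L n_H)``:
    ``r = d / sqrt(d^2 + a)``, which reduces to ``d / sqrt(d^2 + 4)`` at
    equal n.  Positive when the high-relatedness arm has the higher mean.
    """
    if low.n_groups < 2 or high.n_groups < 2:
        raise ValueError("both arms need n_groups >= 2")
    nl, nh = low.n_groups, high.n_groups
    pooled_var = ((nl - 1) * low.sd**2 + (nh - 1) * high.sd**2) / (nl + nh - 2)
    diff = high.mean - low.mean
    if pooled_var == 0:
        if diff == 0:
            return 0.0
        raise ValueError("pooled SD is zero with unequal means (infinite d)")
    d = diff / math.sqrt(pooled_var)
    a = (nl + nh) ** 2 / (nl * nh)
    return d / math.sqrt(d**2 + a)


def fisher_z(r: float, n_groups: int) -> tuple[float, float]:
    """Fisher z-transform with its sampling variance ``1/(n - 3)``.

    ``n_groups`` is the number of groups the correlation was computed
    over; studies with fewer than four groups carry no usable variance.
    """
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1 (Zr infinite at |r| = 1)")
    if n_groups <= 3:
        raise ValueError("n_groups must be >= 4 for a positive sampling variance")
    return math.atanh(r), 1.0 / (n_groups - 3)


def resample_r_from_summaries(
    group_stats: Sequence[tuple[float, float, float, float]],
    n_datasets: int = 1000,
    seed: int | np.random.Generator | None = None,
    clip_range: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of ``r`` from per-group descriptive statistics.

    ``group_stats`` holds one ``(relatedness_mean, relatedness_sd,
    outcome_mean, outcome_sd)`` tuple per group.  For each of
    ``n_datasets`` replicates one value per group is drawn independently
    for relatedness and outcome from normal distributions with the
    stated means and SDs, the Pearson correlation across groups is
    computed, and the average over replicates is returned along with the
    replicate SD.

    Draws are from untruncated normals; ``clip_range`` optionally clips
    outcome draws to a natural range (e.g. proportions), default off.

    Returns
    -------
    (mean_r, sd_r)
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    stats = np.asarray(group_stats, dtype=float)
    if stats.ndim != 2 or stats.shape[1] != 4:
        raise ValueError("group_stats must be (k, 4): rel mean/sd, outcome mean/sd")
    k = stats.shape[0]
    if k < 4:
        raise ValueError("need at least 4 groups to correlate")
    if (stats[:, [1, 3]] < 0).any():
        raise ValueError("SDs must be non-negative")
    if np.ptp(stats[:, 2]) == 0 and (stats[:, 3] == 0).all():
        raise ValueError("all outcome means and SDs identical: r undefined")
    if np.ptp(stats[:, 0]) == 0 and (stats[:, 1] == 0).all():
        raise ValueError("all relatedness means and SDs identical: r undefined")
    rng = np.random.default_rng(seed)
    rel = stats[:, 0] + stats[:, 1] * rng.standard_normal((n_datasets, k))
    out = stats[:, 2] + stats[:, 3] * rng.standard_normal((n_datasets, k))
    if clip_range is not None:
        out = np.clip(out, *clip_range)
    rel_c = rel - rel.mean(axis=1, keepdims=True)
    out_c = out - out.mean(axis=1, keepdims=True)
    denom = np.sqrt((rel_c**2).sum(axis=1) * (out_c**2).sum(axis=1))
    if (denom == 0).any():
        raise ValueError("degenerate replicate with zero variance")
    rs = (rel_c * out_c).sum(axis=1) / denom
    return float(rs.mean()), float(rs.std(ddof=1)) if n_datasets > 1 else 0.0


def _cv_log(arm: GroupSummary) -> float:
    if arm.mean <= 0 or arm.sd <= 0:
        raise ValueError("LnCVR needs positive mean and SD in both arms")
    if arm.n_groups < 2:
        raise ValueError("LnCVR needs n_groups >= 2 in both arms")
    return math.log(arm.sd / arm.mean) + 1.0 / (2 * (arm.n_groups - 1))


def lncvr(low: GroupSummary, high: GroupSummary) -> float:
    """Log coefficient-of-variation ratio, high vs low relatedness.

    ``ln(CV_H) - ln(CV_L)`` with the small-sample correction
    ``+ 1/(2(n - 1))`` applied per arm (the corrections cancel at equal
    n).  Positive values mean the outcome is *more variable across
    groups* under high relatedness.
    """
    return _cv_log(high) - _cv_log(low)


def _lncvr_arm_terms(arm: GroupSummary) -> tuple[float, float]:
    if arm.mean <= 0:
        raise ValueError("arm mean must be positive")
    if arm.n_groups < 2:
        raise ValueError("arm n_groups must be >= 2")
    return arm.sd**2 / (arm.n_groups * arm.mean**2), 1.0 / (2 * (arm.n_groups - 1))


def lncvr_variance(
    low: GroupSummary,
    high: GroupSummary,
    rho_low: float = 0.0,
    rho_high: float = 0.0,
) -> float:
    """Sampling variance of the LnCVR.

    Per arm the variance contribution is
    ``s^2/(n x̄^2) + 1/(2(n-1)) - 2 ρ sqrt(s^2/(n x̄^2) · 1/(2(n-1)))``
    where ρ is the correlation between log mean and log SD across arms
    (mean–variance coupling); the two arm contributions add.  ρ defaults
    to 0; :func:`log_mean_sd_correlation` estimates it from a dataset.
    """
    for rho in (rho_low, rho_high):
        if not -1 <= rho <= 1:
            raise ValueError("rho must lie in [-1, 1]")
    total = 0.0
    for arm, rho in ((low, rho_low), (high, rho_high)):
        a, b = _lncvr_arm_terms(arm)
        total += a + b - 2 * rho * math.sqrt(a * b)
    if total <= 0:
        raise ValueError(
            "non-positive sampling variance; check rho against arm terms"
        )
    return total


def log_mean_sd_correlation(
    means: Sequence[float], sds: Sequence[float], min_arms: int = 4
) -> float:
    """Empirical correlation of ln(mean) and ln(SD) across arms.

    Used as the default ρ in :func:`lncvr_variance`.  Falls back to 0
    when fewer than ``min_arms`` arms with positive mean and SD exist,
    or when either log series is constant.
    """
    m = np.asarray(means, dtype=float)
    s = np.asarray(sds, dtype=float)
    keep = (m > 0) & (s > 0)
    if keep.sum() < min_arms:
        return 0.0
    lm, ls = np.log(m[keep]), np.log(s[keep])
    if np.ptp(lm) == 0 or np.ptp(ls) == 0:
        return 0.0
    return float(np.corrcoef(lm, ls)[0, 1])


def sd_from_dispersion(value: float, kind: str, n_groups: int | None = None) -> float:
    """Convert a reported dispersion (SD, SE or 95% CI half-width) to SD.

    ``se -> se * sqrt(n)``; a 95% CI half-width is first divided by 1.96
    to recover the SE.  ``kind='sd'`` passes through.
    """
    if value < 0:
        raise ValueError("dispersion value must be non-negative")
    if kind == "sd":
        return value
    if kind not in {"se", "ci95"}:
        raise ValueError(f"unsupported dispersion kind: {kind!r}")
    if n_groups is None or n_groups < 2:
        raise ValueError("se/ci95 conversion needs n_groups >= 2")
    se = value / 1.96 if kind == "ci95" else value
    return se * math.sqrt(n_groups)


def reverse_survival_signs(
    records: pd.DataFrame,
    survival_mask: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Flip effect-size signs for records reporting survival.

    Meta-analysed values are on the mortality scale: positive means
    mortality (or pathogen abundance) increases with relatedness.
    Studies reporting *survival* have the opposite polarity and are
    sign-flipped exactly once, tracked by a ``sign_flipped`` provenance
    column; records already flagged are left untouched, making repeated
    application a no-op on them.

    ``survival_mask`` defaults to a ``reported_as_survival`` column if
    present, else no rows.
    """
    out = records.copy()
    if "sign_flipped" not in out.columns:
        out["sign_flipped"] = False
    if survival_mask is None:
        if "reported_as_survival" in out.columns:
            survival_mask = out["reported_as_survival"].astype(bool)
        else:
            survival_mask = pd.Series(False, index=out.index)
    mask = np.asarray(survival_mask, dtype=bool) & ~out["sign_flipped"].to_numpy()
    out.loc[mask, "value"] = -out.loc[mask, "value"]
    out.loc[mask, "sign_flipped"] = True
    return out
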