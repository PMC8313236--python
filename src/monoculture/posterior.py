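"""Posterior summaries and MCMC diagnostics.

Point estimates are posterior modes from a Gaussian kernel density
estimate, intervals are highest-posterior-density (shortest) intervals,
and significance is summarised by pMCMC — twice the smaller tail
fraction of draws relative to a test value, floored at ``2/N`` so a
finite sample never reports an exact zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "PosteriorSummary",
    "posterior_mode",
    "hpd_interval",
    "pmcmc",
    "gelman_rubin",
    "summarize",
]


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior mode, 95% HPD interval and pMCMC for one quantity."""

    pm: float
    ci_low: float
    ci_high: float
    pmcmc: float

    def __post_init__(self) -> None:
        if not self.ci_low < self.ci_high:
            # a point-mass posterior is the only legitimate degenerate case
            if self.ci_low != self.ci_high:
                raise ValueError("ci_low must not exceed ci_high")
        if not 0 < self.pmcmc <= 1:
            raise ValueError("pMCMC must lie in (0, 1]")


def posterior_mode(draws, min_draws: int = 100) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) on a 512-point grid.

    The grid spans the range of the draws.  Degenerate all-equal draws
    return that common value directly.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < min_draws:
        raise ValueError(f"need at least {min_draws} draws, got {x.size}")
    if np.ptp(x) == 0:
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def hpd_interval(draws, mass: float = 0.95, min_draws: int = 100) -> tuple[float, float]:
    """Shortest interval containing ``ceil(mass * N)`` sorted draws."""
    if not 0 < mass <= 1:
        raise ValueError("mass must lie in (0, 1]")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < min_draws:
        raise ValueError(f"need at least {min_draws} draws, got {n}")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def pmcmc(draws, test_value: float = 0.0) -> float:
    """Twice the smaller tail fraction relative to ``test_value``.

    Floored at ``2/N`` (a finite posterior sample cannot support a
    smaller p) and capped at 1.
    """
    x = np.asarray(draws, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 draws")
    above = np.mean(x > test_value)
    below = np.mean(x < test_value)
    if above == 0 and below == 0:
        # every draw sits exactly at the test value: no evidence either way
        return 1.0
    return min(1.0, 2.0 * max(1.0 / n, min(above, below)))


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor for one parameter.

    ``chains`` is (m, n): m >= 2 chains of equal length n >= 10.  The
    statistic is ``sqrt(((n-1)/n * W + B/n) / W)`` with B the
    between-chain and W the within-chain variance, floored at 1.0
    (values below 1 are a finite-sample artifact); a degenerate W of 0
    with no between-chain spread reports exactly 1.0.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = x.shape
    if n < 10:
        raise ValueError("chains too short for a meaningful PSRF")
    means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = means.var(ddof=1)  # = B / n
    if W == 0:
        return 1.0 if B_over_n == 0 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return max(1.0, float(np.sqrt(var_plus / W)))


def summarize(draws, mass: float = 0.95, test_value: float = 0.0) -> PosteriorSummary:
    """Bundle PM, HPD interval and pMCMC for one vector of draws."""
    lo, hi = hpd_interval(draws, mass=mass)
    return PosteriorSummary(
        pm=posterior_mode(draws),
        ci_low=lo,
        ci_high=hi,
        pmcmc=pmcmc(draws, test_value=test_value),
    )
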