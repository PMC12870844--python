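"""Bias-corrected and accelerated (BCa) bootstrap intervals.

The BCa interval corrects the percentile bootstrap for median bias
(``z0``, estimated from the fraction of bootstrap statistics below the
observed one) and for skewness (acceleration ``a``, estimated from the
jackknife influence values). Both corrections shift the percentile
endpoints; with ``z0 = a = 0`` the interval reduces to the plain
percentile interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class BootstrapSummary:
    """Point summary plus a BCa interval for a resampled statistic."""

    estimate: float
    mean_boot: float
    ci_low: float
    ci_high: float
    n_boot: int


def bca_interval(
    theta_hat: float,
    boot_stats: np.ndarray,
    jackknife_stats: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """BCa interval endpoints from precomputed bootstrap and jackknife statistics.

    Degenerate bootstrap distributions (all replicates equal) collapse the
    interval to that constant.
    """
    boot = np.asarray(boot_stats, dtype=float)
    jack = np.asarray(jackknife_stats, dtype=float)
    if boot.size == 0:
        raise ValueError("need at least one bootstrap replicate")
    if np.allclose(boot, boot[0]):
        return float(boot[0]), float(boot[0])

    prop = np.mean(boot < theta_hat)
    # guard the probit against 0/1 when theta_hat sits outside the bootstrap range
    prop = np.clip(prop, 1.0 / (boot.size + 1), boot.size / (boot.size + 1.0))
    z0 = stats.norm.ppf(prop)

    jmean = jack.mean()
    diffs = jmean - jack
    denom = np.sum(diffs**2) ** 1.5
    accel = 0.0 if denom == 0 else np.sum(diffs**3) / (6.0 * denom)

    z_lo = stats.norm.ppf(alpha / 2.0)
    z_hi = stats.norm.ppf(1.0 - alpha / 2.0)
    a_lo = stats.norm.cdf(z0 + (z0 + z_lo) / (1.0 - accel * (z0 + z_lo)))
    a_hi = stats.norm.cdf(z0 + (z0 + z_hi) / (1.0 - accel * (z0 + z_hi)))
    lo, hi = np.quantile(boot, [a_lo, a_hi])
    return float(lo), float(hi)


def bootstrap_statistic(
    data: np.ndarray,
    statistic,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Plain nonparametric bootstrap of ``statistic`` over a 1-d sample."""
    data = np.asarray(data, dtype=float)
    n = data.size
    out = np.empty(n_boot)
    for b in range(n_boot):
        out[b] = statistic(data[rng.integers(0, n, size=n)])
    return out


def jackknife_statistic(data: np.ndarray, statistic) -> np.ndarray:
    """Leave-one-out statistics over a 1-d sample."""
    data = np.asarray(data, dtype=float)
    n = data.size
    idx = np.arange(n)
    return np.array([statistic(data[idx != i]) for i in range(n)])


def bca_summary(
    data: np.ndarray,
    statistic,
    n_boot: int,
    alpha: float,
    rng: np.random.Generator,
) -> BootstrapSummary:
    """Bootstrap a statistic of a 1-d sample and summarize it with a BCa CI."""
    data = np.asarray(data, dtype=float)
    if data.size < 3:
        raise ValueError("need at least 3 observations to bootstrap")
    if n_boot < 100:
        import warnings

        warnings.warn(f"n_boot={n_boot} is small for a BCa interval", stacklevel=2)
    theta_hat = float(statistic(data))
    boot = bootstrap_statistic(data, statistic, n_boot, rng)
    jack = jackknife_statistic(data, statistic)
    lo, hi = bca_interval(theta_hat, boot, jack, alpha)
    return BootstrapSummary(
        estimate=theta_hat,
        mean_boot=float(boot.mean()),
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
    )
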