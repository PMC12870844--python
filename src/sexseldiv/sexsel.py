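"""Strength of sexual selection from mating-population assays.

Three standard indices are estimated per sex and regime from lifetime
mating counts and reproductive success:

* the opportunity for sexual selection ``I_s`` — the variance in relative
  mating success, an upper bound on standardized selection through mating;
* the Bateman gradient ``beta_B`` — the slope of relative reproductive
  success on absolute mating success, fitted in a linear mixed model with
  replicate line as a random intercept (lines within a regime are assumed
  to share a common gradient);
* the Jones index ``s'_max = sqrt(I_s) * beta_ss`` — the maximum
  standardized strength of sexual selection, where ``beta_ss`` is the
  ordinary least-squares slope of relative reproductive success on
  relative mating success.

Individuals with zero matings (and hence zero reproductive success) are
excluded before estimation; gradients are compared between regimes with a
two-estimate Z test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .bootstrap import bca_summary
from .config import REGIMES, SEXES, RunConfig


@dataclass(frozen=True)
class SexSelEstimates:
    """Selection indices for one sex x regime cell."""

    sex: str
    regime: str
    n_used: int
    n_excluded_zero: int
    I_s: float
    I_s_ci: tuple[float, float]
    beta_B: float
    beta_B_se: float
    beta_ss: float
    s_max: float


@dataclass(frozen=True)
class SlopeEqualityTest:
    """Z test of equal Bateman gradients between the two regimes."""

    sex: str
    z: float
    p: float


def exclude_zero_success(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop individuals that never mated (matings == 0); return count removed."""
    retained = records[records["matings"] >= 1]
    return retained, int(len(records) - len(retained))


def relativize(values, grouping=None) -> np.ndarray:
    """Divide each value by its group mean, so every group averages to 1.

    ``grouping`` defaults to a single group. A group with mean zero is an
    error (relative fitness undefined), reported by group label.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    if (s < 0).any():
        raise ValueError("values must be non-negative")
    groups = pd.Series(["all"] * len(s)) if grouping is None else pd.Series(list(grouping))
    means = s.groupby(groups.values).transform("mean")
    zero_groups = sorted(set(groups[means == 0]))
    if zero_groups:
        raise ValueError(f"group(s) {zero_groups} have mean 0; cannot relativize")
    return (s / means).to_numpy()


def opportunity_for_selection(relative_matings) -> float:
    """Sample variance (n-1 divisor) of relative mating success."""
    x = np.asarray(relative_matings, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to estimate a variance")
    return float(np.var(x, ddof=1))


def bateman_gradient(records: pd.DataFrame, rel_offspring=None) -> tuple[float, float]:
    """Mixed-model Bateman gradient for one sex x regime subset.

    Fits relative reproductive success ~ absolute mating count with a
    random intercept per replicate line (REML) and returns the fixed slope
    and its Wald SE. With a single line, or when the estimated line
    variance is zero, the fit degrades to ordinary least squares.
    """
    x = records["matings"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("no variance in mating counts; gradient unidentifiable")
    if rel_offspring is None:
        rel_offspring = relativize(records["offspring"].to_numpy(dtype=float))
    y = np.asarray(rel_offspring, dtype=float)
    lines = records["line_id"].to_numpy()

    def _ols() -> tuple[float, float]:
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        return float(fit.params[1]), float(fit.bse[1])

    if len(np.unique(lines)) < 2:
        return _ols()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, sm.add_constant(x), groups=lines)
            fit = model.fit(reml=True)
        if not np.isfinite(fit.params[1]) or np.asarray(fit.cov_re)[0, 0] < 1e-10:
            return _ols()
        return float(fit.params[1]), float(fit.bse[1])
    except (np.linalg.LinAlgError, ValueError):
        return _ols()


def ss_slope(relative_offspring, relative_matings) -> float:
    """OLS slope of relative reproductive success on relative mating success."""
    x = np.asarray(relative_matings, dtype=float)
    y = np.asarray(relative_offspring, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need equal-length inputs with at least 2 points")
    vx = np.var(x)
    if vx == 0:
        raise ValueError("no variance in relative mating success")
    return float(np.cov(x, y, bias=True)[0, 1] / vx)


def jones_index(I_s: float, beta_ss: float) -> float:
    """Jones index s'_max = sqrt(I_s) * beta_ss."""
    if I_s < 0:
        raise ValueError("I_s must be non-negative")
    return float(np.sqrt(I_s) * beta_ss)


def slope_equality_test(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Two-independent-estimates Z test of equal slopes; two-sided p."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (b1 - b2) / np.hypot(se1, se2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def analyze_sexual_selection(
    records: pd.DataFrame,
    config: RunConfig | None = None,
    relativize_by: str = "regime",
) -> tuple[list[SexSelEstimates], list[SlopeEqualityTest]]:
    """Estimate all indices per sex x regime and test slope equality per sex.

    ``relativize_by`` is ``"regime"`` (divide by the sex x regime mean, the
    primary choice) or ``"population"`` (divide by the mating-population
    mean).
    """
    if relativize_by not in ("regime", "population"):
        raise ValueError("relativize_by must be 'regime' or 'population'")
    config = config or RunConfig()
    estimates: list[SexSelEstimates] = []
    slopes: dict[tuple[str, str], tuple[float, float]] = {}
    for sex in SEXES:
        for regime in REGIMES:
            cell = records[(records["sex"] == sex) & (records["regime"] == regime)]
            if cell.empty:
                continue
            retained, n_excl = exclude_zero_success(cell)
            if len(retained) < 3:
                raise ValueError(f"too few individuals after exclusion for {sex}/{regime}")
            grouping = retained["mating_population_id"] if relativize_by == "population" else None
            rel_mat = relativize(retained["matings"].to_numpy(dtype=float), grouping)
            rel_off = relativize(retained["offspring"].to_numpy(dtype=float), grouping)
            I_s = opportunity_for_selection(rel_mat)
            boot = bca_summary(
                rel_mat,
                lambda v: np.var(v, ddof=1),
                config.n_bootstrap,
                config.alpha,
                config.rng(f"sexsel-Is-{sex}-{regime}"),
            )
            beta_B, beta_B_se = bateman_gradient(retained, rel_off)
            b_ss = ss_slope(rel_off, rel_mat)
            estimates.append(
                SexSelEstimates(
                    sex=sex,
                    regime=regime,
                    n_used=len(retained),
                    n_excluded_zero=n_excl,
                    I_s=I_s,
                    I_s_ci=(boot.ci_low, boot.ci_high),
                    beta_B=beta_B,
                    beta_B_se=beta_B_se,
                    beta_ss=b_ss,
                    s_max=jones_index(I_s, b_ss),
                )
            )
            slopes[(sex, regime)] = (beta_B, beta_B_se)
    tests: list[SlopeEqualityTest] = []
    for sex in SEXES:
        if (sex, "WSS") in slopes and (sex, "SSS") in slopes:
            b1, se1 = slopes[(sex, "SSS")]
            b2, se2 = slopes[(sex, "WSS")]
            z, p = slope_equality_test(b1, se1, b2, se2)
            tests.append(SlopeEqualityTest(sex=sex, z=z, p=p))
    return estimates, tests


def estimates_table(estimates: list[SexSelEstimates]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append(
            {
                "sex": e.sex,
                "regime": e.regime,
                "n_used": e.n_used,
                "n_excluded_zero": e.n_excluded_zero,
                "I_s": e.I_s,
                "I_s_ci_low": e.I_s_ci[0],
                "I_s_ci_high": e.I_s_ci[1],
                "beta_B": e.beta_B,
                "beta_B_se": e.beta_B_se,
                "beta_ss": e.beta_ss,
                "s_max": e.s_max,
            }
        )
    return pd.DataFrame(rows)
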