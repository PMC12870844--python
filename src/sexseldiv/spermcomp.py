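"""Last-male sperm-competition success (P2) in a fully crossed line design.

P2 — the proportion of a doubly-mated female's eggs that hatch, i.e. the
share sired by the second (fertile) male under the sterile-male technique —
is analyzed per regime with a quasi-binomial logit GLM whose sequential
terms are male line, female line and their interaction. The strength of
the male x female interaction is then compared between regimes by three
complementary routes:

1. a binomial GLMM (PQL with the dispersion fixed at the quasi-binomial
   estimate) from which the logit-scale interaction variance component and
   its SE are extracted;
2. a weighted (by egg count) ANOVA of arcsine-square-root P2, giving the
   interaction's share of variance per regime and a variance-ratio F test
   between regimes;
3. a no-interaction (additive) model whose per-cell mean residuals measure
   deviation from additivity; the variance of these cell means is
   bootstrapped (BCa) and compared between regimes by a variance-ratio F
   test and Bartlett's test.

A rank-sum comparison of within-line vs between-line crosses checks for
consistent directionality (own-line advantage) in sperm precedence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
import statsmodels.api as sm

from .bootstrap import bca_interval
from .config import REGIMES, RunConfig

__all__ = [
    "filter_competing_females",
    "compute_p2",
    "arcsine_sqrt",
    "fit_crossed_glm",
    "interaction_variance_component",
    "interaction_variance_component_moments",
    "lmm_share_and_ratio_test",
    "residual_cell_bootstrap",
    "within_vs_between_comparison",
    "analyze_sperm_competition",
    "CrossedModelResult",
    "InteractionComparison",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class CrossedModelResult:
    """Quasi-binomial crossed GLM summary for one regime."""

    regime: str
    deviance_table: pd.DataFrame  # rows: male line, female line, interaction, residual
    dispersion: float
    predicted_mean_p2: float
    predicted_mean_ci: tuple[float, float]
    eta_squared_interaction: float


@dataclass
class ResidualBootstrapResult:
    """Cell-mean residual variances with BCa CIs and between-regime tests."""

    variance_by_regime: dict[str, float]
    mean_boot_variance_by_regime: dict[str, float]
    ci_by_regime: dict[str, tuple[float, float]]
    f_ratio: float
    f_df: tuple[int, int]
    p_one_sided: float
    p_two_sided: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


@dataclass
class LmmShareResult:
    """Arcsine-square-root weighted ANOVA route."""

    share_by_regime: dict[str, float]  # % of total (weighted) SS
    interaction_ms_by_regime: dict[str, float]
    f_ratio: float
    f_df: tuple[int, int]
    p_one_sided: float
    p_two_sided: float


@dataclass
class InteractionComparison:
    """All three inferential routes plus the within/between rank-sum check."""

    varcomp_by_regime: dict[str, tuple[float, float]]  # (variance, SE), logit scale
    lmm: LmmShareResult
    residual: ResidualBootstrapResult
    within_vs_between_p: dict[str, float]


# ---------------------------------------------------------------------------
# elementary operations


def filter_competing_females(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only females where two ejaculates demonstrably competed.

    Excluded: females missing either mating, with no eggs, or with zero
    hatched offspring (the focal male transferred no effective ejaculate).
    """
    mask = (
        records["first_mating_ok"]
        & records["second_mating_ok"]
        & (records["eggs_total"] >= 1)
        & (records["hatched"] >= 1)
    )
    return records[mask]


def compute_p2(records: pd.DataFrame) -> pd.Series:
    """P2 = hatched / total eggs laid, per female."""
    if (records["eggs_total"] < 1).any():
        raise ValueError("P2 undefined for females with zero eggs")
    return records["hatched"] / records["eggs_total"]


def arcsine_sqrt(p) -> np.ndarray:
    """Variance-stabilizing arcsine-square-root transform of a proportion."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(p))


def _check_complete_design(records: pd.DataFrame) -> tuple[list, list]:
    males = sorted(records["male_line"].unique())
    females = sorted(records["female_line"].unique())
    counts = records.groupby(["male_line", "female_line"]).size()
    for m in males:
        for f in females:
            if (m, f) not in counts.index:
                raise ValueError(f"empty design cell: male line {m!r} x female line {f!r}")
    return males, females


def _glm_endog(records: pd.DataFrame) -> np.ndarray:
    y = records["hatched"].to_numpy(dtype=float)
    m = records["eggs_total"].to_numpy(dtype=float)
    return np.column_stack([y, m - y])


# ---------------------------------------------------------------------------
# route 0: the per-regime quasi-binomial crossed GLM (Table-1 style)


def fit_crossed_glm(records: pd.DataFrame, term_order: tuple[str, str] = ("male_line", "female_line")) -> CrossedModelResult:
    """Sequential quasi-binomial logit GLM: male line, female line, interaction.

    The dispersion is estimated as Pearson chi-square over residual df of
    the full model; each term's F statistic is (delta deviance / delta df)
    divided by the dispersion, referred to an F distribution on (delta df,
    residual df). eta^2 of the interaction is its deviance share of the
    total (terms + residual) deviance.
    """
    _check_complete_design(records)
    regime_vals = records["regime"].unique()
    regime = str(regime_vals[0]) if len(regime_vals) == 1 else "mixed"

    import patsy

    df = records.copy()
    endog = _glm_endog(df)
    first, second = term_order
    formulas = [
        "1",
        f"C({first})",
        f"C({first}) + C({second})",
        f"C({first}) * C({second})",
    ]
    fits = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rhs in formulas:
            X = patsy.dmatrix(rhs, df, return_type="dataframe")
            fits.append(sm.GLM(endog, X, family=sm.families.Binomial()).fit(maxiter=200))

    full = fits[-1]
    df_resid = int(full.df_resid)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom: need replicate females per cell")
    dispersion = float(full.pearson_chi2 / df_resid)

    devs = [f.deviance for f in fits]
    dfs_model = [int(f.df_model) for f in fits]
    term_names = [f"{first} (line)", f"{second} (line)", "male x female"]
    rows = []
    for i, name in enumerate(term_names):
        d_dev = devs[i] - devs[i + 1]
        d_df = dfs_model[i + 1] - dfs_model[i]
        F = (d_dev / d_df) / dispersion
        p = float(stats.f.sf(F, d_df, df_resid))
        rows.append({"term": name, "df": d_df, "deviance": d_dev, "F": F, "p": p})
    rows.append({"term": "residual", "df": df_resid, "deviance": devs[-1], "F": np.nan, "p": np.nan})
    table = pd.DataFrame(rows)

    # predicted mean P2: inverse logit of the average cell linear predictor,
    # with a delta-method CI using the dispersion-scaled coefficient covariance
    cells = df.drop_duplicates([first, second])[[first, second]].sort_values([first, second])
    Xc = patsy.dmatrix(formulas[-1], cells, return_type="dataframe").to_numpy()
    eta_cells = Xc @ full.params.to_numpy()
    if np.any(np.abs(eta_cells) > 10):
        warnings.warn(
            "near-complete separation in at least one design cell; "
            "clipping the cell linear predictor for the mean-P2 summary"
        )
        eta_cells = np.clip(eta_cells, -10, 10)
    g = Xc.mean(axis=0)
    eta_bar = float(g @ full.params.to_numpy())
    var_eta = float(g @ (dispersion * full.cov_params().to_numpy()) @ g)
    zq = stats.norm.ppf(0.975)
    lo, hi = eta_bar - zq * np.sqrt(var_eta), eta_bar + zq * np.sqrt(var_eta)
    expit = lambda t: 1.0 / (1.0 + np.exp(-t))

    total_dev = sum(r["deviance"] for r in rows)
    eta2 = rows[2]["deviance"] / total_dev if total_dev > 0 else 0.0

    return CrossedModelResult(
        regime=regime,
        deviance_table=table,
        dispersion=dispersion,
        predicted_mean_p2=float(expit(eta_bar)),
        predicted_mean_ci=(float(expit(lo)), float(expit(hi))),
        eta_squared_interaction=float(eta2),
    )


# ---------------------------------------------------------------------------
# route 1: PQL GLMM interaction variance component


def _weighted_reml_nll(sigma2: np.ndarray, z: np.ndarray, X: np.ndarray, Zs: list[np.ndarray], w: np.ndarray, phi: float) -> float:
    """-2 x restricted log-likelihood of the working LMM, dispersion fixed.

    V = phi * diag(1/w) + sum_k sigma2_k Z_k Z_k'.
    """
    n = z.size
    V = np.diag(phi / w)
    for s2, Z in zip(sigma2, Zs):
        if s2 > 0:
            V += s2 * (Z @ Z.T)
    try:
        c, low = linalg.cho_factor(V, check_finite=False)
    except linalg.LinAlgError:
        return 1e12
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_X = linalg.cho_solve((c, low), X, check_finite=False)
    Vi_z = linalg.cho_solve((c, low), z, check_finite=False)
    XtViX = X.T @ Vi_X
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(XtViX, X.T @ Vi_z)
    r = z - X @ beta
    Vi_r = linalg.cho_solve((c, low), r, check_finite=False)
    return float(logdet_V + logdet_XtViX + r @ Vi_r)


def _reml_blup(sigma2, z, X, Zs, w, phi):
    V = np.diag(phi / w)
    for s2, Z in zip(sigma2, Zs):
        if s2 > 0:
            V += s2 * (Z @ Z.T)
    c, low = linalg.cho_factor(V, check_finite=False)
    Vi_X = linalg.cho_solve((c, low), X, check_finite=False)
    Vi_z = linalg.cho_solve((c, low), z, check_finite=False)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_z)
    r = z - X @ beta
    Vi_r = linalg.cho_solve((c, low), r, check_finite=False)
    eta = X @ beta
    for s2, Z in zip(sigma2, Zs):
        if s2 > 0:
            eta = eta + s2 * (Z @ (Z.T @ Vi_r))
    return beta, eta


def _dummies(labels: pd.Series) -> np.ndarray:
    return pd.get_dummies(labels.astype(str)).to_numpy(dtype=float)


def interaction_variance_component(
    records: pd.DataFrame,
    dispersion: float | None = None,
    max_outer: int = 50,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Logit-scale variance of the male x female interaction from a binomial GLMM.

    Penalized quasi-likelihood: the working linear mixed model has random
    effects for male line, female line and their interaction, an
    intercept-only fixed part, and residual variance fixed at the
    dispersion estimated from the corresponding fixed-effects
    quasi-binomial fit (inner fits are weighted REML over the three
    variance components). The SE comes from the numerical Hessian of the
    restricted likelihood at the optimum. The procedure is deterministic.
    """
    _check_complete_design(records)
    if dispersion is None:
        dispersion = fit_crossed_glm(records).dispersion
    phi = float(dispersion)

    y = records["hatched"].to_numpy(dtype=float)
    m = records["eggs_total"].to_numpy(dtype=float)
    Zm = _dummies(records["male_line"])
    Zf = _dummies(records["female_line"])
    Zc = _dummies(records["male_line"].astype(str) + ":" + records["female_line"].astype(str))
    Zs = [Zm, Zf, Zc]
    X = np.ones((len(records), 1))

    # initialize eta from continuity-corrected empirical logits per cell
    cell = records["male_line"].astype(str) + ":" + records["female_line"].astype(str)
    agg = pd.DataFrame({"y": y, "m": m, "cell": cell}).groupby("cell").sum()
    elogit = np.log((agg["y"] + 0.5) / (agg["m"] - agg["y"] + 0.5))
    eta = cell.map(elogit).to_numpy(dtype=float)

    sigma2 = np.array([0.05, 0.05, 0.1])
    converged = False
    for _ in range(max_outer):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = m * mu * (1.0 - mu)
        z = eta + (y - m * mu) / w

        res = optimize.minimize(
            _weighted_reml_nll,
            sigma2,
            args=(z, X, Zs, w, phi),
            method="L-BFGS-B",
            bounds=[(0.0, 50.0)] * 3,
        )
        new_sigma2 = res.x
        _, new_eta = _reml_blup(new_sigma2, z, X, Zs, w, phi)
        delta = max(np.max(np.abs(new_sigma2 - sigma2)), np.max(np.abs(new_eta - eta)))
        sigma2, eta = new_sigma2, new_eta
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("PQL outer loop did not fully converge; returning last iterate")

    # SE of the interaction component from the REML curvature at the optimum
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = m * mu * (1.0 - mu)
    z = eta + (y - m * mu) / w
    se = _hessian_se(sigma2, z, X, Zs, w, phi, index=2)
    return float(sigma2[2]), float(se)


def interaction_variance_component_moments(
    records: pd.DataFrame, dispersion: float | None = None
) -> tuple[float, float]:
    """Method-of-moments interaction variance from cell empirical logits.

    Robust fallback for :func:`interaction_variance_component`: pool each
    cell's hatched/eggs, take continuity-corrected empirical logits, remove
    grand mean and the two line main effects, and subtract the
    dispersion-scaled binomial sampling variance of a cell logit from the
    interaction mean square. Unlike PQL this does not attenuate under
    strong overdispersion, at the price of a cruder (normal-theory) SE.
    """
    _check_complete_design(records)
    if dispersion is None:
        dispersion = fit_crossed_glm(records).dispersion
    g = records.groupby(["male_line", "female_line"]).agg(
        y=("hatched", "sum"), m=("eggs_total", "sum")
    )
    n_m = g.index.get_level_values(0).nunique()
    n_f = g.index.get_level_values(1).nunique()
    elogit = np.log((g["y"] + 0.5) / (g["m"] - g["y"] + 0.5)).rename("elogit")
    p = g["y"] / g["m"]
    sampling_var = float((dispersion / (g["m"] * p * (1 - p))).mean())
    df = elogit.reset_index()
    grand = df["elogit"].mean()
    a = df.groupby("male_line")["elogit"].mean() - grand
    b = df.groupby("female_line")["elogit"].mean() - grand
    resid = df["elogit"] - grand - df["male_line"].map(a) - df["female_line"].map(b)
    df_int = (n_m - 1) * (n_f - 1)
    ms_int = float((resid**2).sum() / df_int)
    var = max(0.0, ms_int - sampling_var)
    se = np.sqrt(2.0 / df_int) * ms_int
    return var, float(se)


def _hessian_se(sigma2, z, X, Zs, w, phi, index: int) -> float:
    k = len(sigma2)
    h = np.maximum(1e-4, 1e-2 * np.abs(sigma2))
    H = np.zeros((k, k))

    def f(s):
        return 0.5 * _weighted_reml_nll(np.maximum(s, 0.0), z, X, Zs, w, phi)

    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(sigma2 + ei + ej) - f(sigma2 + ei - ej) - f(sigma2 - ei + ej) + f(sigma2 - ei - ej)
            ) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        var = cov[index, index]
        return float(np.sqrt(var)) if var > 0 else float("nan")
    except np.linalg.LinAlgError:
        return float("nan")


# ---------------------------------------------------------------------------
# route 2: weighted arcsine-square-root ANOVA and variance-ratio test


def _weighted_anova(records: pd.DataFrame) -> dict:
    """Sequential weighted two-way ANOVA of arcsine-sqrt P2 (weights = eggs)."""
    import patsy

    _check_complete_design(records)
    df = records.copy()
    df["y"] = arcsine_sqrt(compute_p2(df))
    wts = df["eggs_total"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)

    rss = []
    dfs = []
    for rhs in ["1", "C(male_line)", "C(male_line) + C(female_line)", "C(male_line) * C(female_line)"]:
        X = patsy.dmatrix(rhs, df, return_type="dataframe")
        fit = sm.WLS(y, X, weights=wts).fit()
        rss.append(float(fit.ssr))
        dfs.append(int(fit.df_resid))
    ss_int = rss[2] - rss[3]
    df_int = dfs[2] - dfs[3]
    return {
        "ss_total": rss[0],
        "ss_male": rss[0] - rss[1],
        "ss_female": rss[1] - rss[2],
        "ss_interaction": ss_int,
        "df_interaction": df_int,
        "ms_interaction": ss_int / df_int,
        "ss_residual": rss[3],
        "df_residual": dfs[3],
    }


def lmm_share_and_ratio_test(records_wss: pd.DataFrame, records_sss: pd.DataFrame) -> LmmShareResult:
    """Interaction share of variance per regime plus a between-regime F test.

    Responses are arcsine-square-root P2 weighted by total egg count; the
    share is the interaction's percentage of the total weighted sum of
    squares, and the F ratio compares the interaction mean squares
    (SSS over WSS), one-sided for the directional prediction that the
    interaction is stronger under strong sexual selection.
    """
    a_wss = _weighted_anova(records_wss)
    a_sss = _weighted_anova(records_sss)
    F = a_sss["ms_interaction"] / a_wss["ms_interaction"]
    df_pair = (a_sss["df_interaction"], a_wss["df_interaction"])
    p_one = float(stats.f.sf(F, *df_pair))
    p_two = float(2 * min(stats.f.sf(F, *df_pair), stats.f.cdf(F, *df_pair)))
    return LmmShareResult(
        share_by_regime={
            "WSS": 100.0 * a_wss["ss_interaction"] / a_wss["ss_total"],
            "SSS": 100.0 * a_sss["ss_interaction"] / a_sss["ss_total"],
        },
        interaction_ms_by_regime={"WSS": a_wss["ms_interaction"], "SSS": a_sss["ms_interaction"]},
        f_ratio=float(F),
        f_df=df_pair,
        p_one_sided=p_one,
        p_two_sided=min(1.0, p_two),
    )


# ---------------------------------------------------------------------------
# route 3: no-interaction residual cell-mean bootstrap


def _cell_residuals(records: pd.DataFrame) -> pd.DataFrame:
    """Offspring-count residuals from the additive (no-interaction) GLM."""
    import patsy

    _check_complete_design(records)
    endog = _glm_endog(records)
    X = patsy.dmatrix("C(male_line) + C(female_line)", records, return_type="dataframe")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit(maxiter=200)
    resid = records["hatched"].to_numpy(dtype=float) - records["eggs_total"].to_numpy(dtype=float) * fit.fittedvalues
    out = records[["male_line", "female_line"]].copy()
    out["resid"] = np.asarray(resid)
    out["cell"] = out["male_line"].astype(str) + ":" + out["female_line"].astype(str)
    return out


def _safe_bartlett(groups: list[np.ndarray]) -> tuple[float, int, float]:
    variances = [np.var(g, ddof=1) for g in groups]
    if np.allclose(variances, variances[0]):
        return 0.0, len(groups) - 1, 1.0
    chi2, p = stats.bartlett(*groups)
    return float(chi2), len(groups) - 1, float(p)


def residual_cell_bootstrap(
    records_by_regime: dict[str, pd.DataFrame],
    n_boot: int = 9999,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ResidualBootstrapResult:
    """Variance of per-cell mean residuals from the additive model, per regime.

    The statistic is the sample variance across design cells of the mean
    offspring-count residual; females are resampled with replacement within
    their cells (preserving the crossed design) for the BCa interval, and
    acceleration comes from a delete-one-female jackknife. Regimes are
    compared with a variance-ratio F test (one-sided, SSS over WSS) and
    Bartlett's test on the two groups of cell means.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small for a BCa interval")
    rng = rng or np.random.default_rng(0)
    variances: dict[str, float] = {}
    mean_boot: dict[str, float] = {}
    cis: dict[str, tuple[float, float]] = {}
    cell_means_by_regime: dict[str, np.ndarray] = {}
    for regime in sorted(records_by_regime):
        res = _cell_residuals(records_by_regime[regime])
        cells = sorted(res["cell"].unique())
        groups = [res.loc[res["cell"] == c, "resid"].to_numpy() for c in cells]
        cell_means = np.array([g.mean() for g in groups])
        theta = float(np.var(cell_means, ddof=1))
        cell_means_by_regime[regime] = cell_means
        variances[regime] = theta

        sizes = np.array([g.size for g in groups])
        boot = np.empty(n_boot)
        for b in range(n_boot):
            means_b = np.array([g[rng.integers(0, g.size, g.size)].mean() for g in groups])
            boot[b] = np.var(means_b, ddof=1)
        # jackknife over females: recompute the cell's mean without that female
        jack = []
        for ci, g in enumerate(groups):
            if g.size < 2:
                continue
            base = cell_means.copy()
            for i in range(g.size):
                base[ci] = (g.sum() - g[i]) / (g.size - 1)
                jack.append(np.var(base, ddof=1))
        lo, hi = bca_interval(theta, boot, np.asarray(jack), alpha)
        mean_boot[regime] = float(boot.mean())
        cis[regime] = (lo, hi)

    if set(variances) >= {"WSS", "SSS"}:
        n_s = cell_means_by_regime["SSS"].size
        n_w = cell_means_by_regime["WSS"].size
        F = variances["SSS"] / variances["WSS"]
        df_pair = (n_s - 1, n_w - 1)
        p_one = float(stats.f.sf(F, *df_pair))
        p_two = float(2 * min(stats.f.sf(F, *df_pair), stats.f.cdf(F, *df_pair)))
        chi2, bdf, bp = _safe_bartlett([cell_means_by_regime["SSS"], cell_means_by_regime["WSS"]])
    else:
        F, df_pair, p_one, p_two = np.nan, (0, 0), np.nan, np.nan
        chi2, bdf, bp = np.nan, 0, np.nan
    return ResidualBootstrapResult(
        variance_by_regime=variances,
        mean_boot_variance_by_regime=mean_boot,
        ci_by_regime=cis,
        f_ratio=float(F),
        f_df=df_pair,
        p_one_sided=p_one,
        p_two_sided=min(1.0, p_two) if np.isfinite(p_two) else p_two,
        bartlett_chi2=chi2,
        bartlett_df=bdf,
        bartlett_p=bp,
    )


# ---------------------------------------------------------------------------
# within- vs between-line crosses


def within_vs_between_comparison(records_by_regime: dict[str, pd.DataFrame]) -> dict[str, float]:
    """One-sided rank-sum p (within-line P2 greater) per regime and combined.

    Exact enumeration for small samples (both groups <= 20), normal
    approximation with tie correction otherwise.
    """

    def _p(within: np.ndarray, between: np.ndarray) -> float:
        method = "exact" if max(within.size, between.size) <= 20 else "asymptotic"
        return float(
            stats.mannwhitneyu(within, between, alternative="greater", method=method).pvalue
        )

    out: dict[str, float] = {}
    pooled_within: list[np.ndarray] = []
    pooled_between: list[np.ndarray] = []
    for regime, rec in sorted(records_by_regime.items()):
        p2 = compute_p2(rec).to_numpy()
        within = p2[(rec["female_line"] == rec["male_line"]).to_numpy()]
        between = p2[(rec["female_line"] != rec["male_line"]).to_numpy()]
        if within.size == 0 or between.size == 0:
            raise ValueError(f"regime {regime}: need both within- and between-line crosses")
        out[regime] = _p(within, between)
        pooled_within.append(within)
        pooled_between.append(between)
    out["combined"] = _p(np.concatenate(pooled_within), np.concatenate(pooled_between))
    return out


# ---------------------------------------------------------------------------
# pipeline


def analyze_sperm_competition(
    records: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[dict[str, CrossedModelResult], InteractionComparison]:
    """Filter, fit the per-regime crossed GLMs, and run all three routes."""
    config = config or RunConfig()
    retained = filter_competing_females(records)
    by_regime = {r: retained[retained["regime"] == r] for r in REGIMES if (retained["regime"] == r).any()}
    if set(by_regime) != set(REGIMES):
        raise ValueError("need double-mating data for both regimes")

    glms = {r: fit_crossed_glm(by_regime[r]) for r in REGIMES}
    varcomp = {
        r: interaction_variance_component(by_regime[r], dispersion=glms[r].dispersion)
        for r in REGIMES
    }
    lmm = lmm_share_and_ratio_test(by_regime["WSS"], by_regime["SSS"])
    residual = residual_cell_bootstrap(
        by_regime, n_boot=config.n_bootstrap, alpha=config.alpha, rng=config.rng("spermcomp-bootstrap")
    )
    wvb = within_vs_between_comparison(by_regime)
    comparison = InteractionComparison(
        varcomp_by_regime=varcomp, lmm=lmm, residual=residual, within_vs_between_p=wvb
    )
    return glms, comparison
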