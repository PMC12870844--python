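"""Between-replicate divergence of gene expression and its SSS/WSS ratio.

The core statistic is, per gene and regime, the mean absolute deviation of
the (normalized) expression values of the replicate lines around their
regime mean; the divergence ratio divides the SSS divergence by the WSS
divergence and equals one when expression has diverged equally under the
two regimes. Designated reproductive-protein gene sets are summarized by a
bootstrap of the median ratio with BCa intervals and compared against the
transcriptome background of the same sex with Kolmogorov-Smirnov and
(when KS rejects) one-sided Mann-Whitney U tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bootstrap import BootstrapSummary, bca_summary
from .config import RunConfig, check_regime, check_sex

logger = logging.getLogger("sexseldiv")


@dataclass
class ExpressionData:
    """A gene x sample expression matrix plus per-sample metadata.

    ``values`` holds normalized expression (genes as rows, samples as
    columns); ``raw_counts``/``library_sizes`` are optional and feed the
    built-in cpm/log-cpm normalization and the expressed-transcript filter.
    ``sample_meta`` is indexed by sample id with columns sex, regime, line.
    """

    values: pd.DataFrame | None
    sample_meta: pd.DataFrame
    raw_counts: pd.DataFrame | None = None
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        check_sex(self.sample_meta["sex"])
        check_regime(self.sample_meta["regime"])
        mat = self.values if self.values is not None else self.raw_counts
        if mat is None:
            raise ValueError("ExpressionData needs values or raw_counts")
        missing = [s for s in mat.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        dup = self.sample_meta.reset_index().duplicated(subset=["sex", "regime", "line"])
        if dup.any():
            raise ValueError("sample metadata has duplicate (sex, regime, line) combinations")

    @property
    def gene_ids(self) -> pd.Index:
        mat = self.values if self.values is not None else self.raw_counts
        return mat.index

    def samples_for(self, sex: str, regime: str | None = None) -> list[str]:
        meta = self.sample_meta
        mask = meta["sex"] == sex
        if regime is not None:
            mask &= meta["regime"] == regime
        return list(meta.index[mask])


@dataclass(frozen=True)
class SetSummary:
    """Set-level divergence-ratio summary and set-vs-background tests."""

    name: str
    sex: str
    n_genes: int
    n_undefined: int
    boot: BootstrapSummary | None
    ks_D: float | None = None
    ks_p: float | None = None
    mw_p_one_sided: float | None = None
    mw_reported: bool = False


@dataclass
class DivergenceResult:
    """Per-gene divergences/ratios per sex plus set-level summaries."""

    per_gene: dict[str, pd.DataFrame]
    per_set: list[SetSummary] = field(default_factory=list)

    def set_table(self) -> pd.DataFrame:
        rows = []
        for s in self.per_set:
            rows.append(
                {
                    "set": s.name,
                    "sex": s.sex,
                    "n_genes": s.n_genes,
                    "n_undefined": s.n_undefined,
                    "median_ratio": s.boot.estimate if s.boot else np.nan,
                    "boot_mean_median": s.boot.mean_boot if s.boot else np.nan,
                    "bca_low": s.boot.ci_low if s.boot else np.nan,
                    "bca_high": s.boot.ci_high if s.boot else np.nan,
                    "ks_D": s.ks_D,
                    "ks_p": s.ks_p,
                    "mw_p_one_sided": s.mw_p_one_sided,
                    "mw_reported": s.mw_reported,
                }
            )
        return pd.DataFrame(rows)


def cpm(raw_counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Counts per million: count / library size x 1e6, per sample column."""
    lib = library_sizes.reindex(raw_counts.columns)
    if (lib <= 0).any() or lib.isna().any():
        raise ValueError("library sizes must be positive for every sample")
    return raw_counts.div(lib, axis=1) * 1e6


def filter_expressed(
    cpm_matrix: pd.DataFrame,
    samples_in_scope: Sequence[str],
    threshold: float = 2.0,
) -> list[str]:
    """Genes whose cpm strictly exceeds ``threshold`` in every in-scope sample."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    samples = list(samples_in_scope)
    if not samples:
        raise ValueError("empty sample scope for the expressed-transcript filter")
    keep = (cpm_matrix[samples] > threshold).all(axis=1)
    return list(cpm_matrix.index[keep])


def normalize(data: ExpressionData, mode: str = "log_cpm") -> ExpressionData:
    """Populate ``values``: log2(cpm + 0.5) from raw counts, or pass through.

    The divergence-ratio method is agnostic to the particular
    variance-stabilizing transformation; any externally normalized matrix
    can be supplied with ``mode="precomputed"``.
    """
    if mode == "precomputed":
        if data.values is None:
            raise ValueError("precomputed mode requires values to be present")
        return data
    if mode == "log_cpm":
        if data.raw_counts is None or data.library_sizes is None:
            raise ValueError("log_cpm mode requires raw_counts and library_sizes")
        values = np.log2(cpm(data.raw_counts, data.library_sizes) + 0.5)
        return ExpressionData(
            values=values,
            sample_meta=data.sample_meta,
            raw_counts=data.raw_counts,
            library_sizes=data.library_sizes,
        )
    raise ValueError(f"unknown normalization mode {mode!r}")


def replicate_divergence(values: np.ndarray) -> float:
    """Mean absolute deviation of replicate-line values around their mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicate values")
    return float(np.mean(np.abs(x - x.mean())))


def divergence_ratio(d_sss: float, d_wss: float) -> float:
    """d_SSS / d_WSS; NaN (undefined) when d_WSS is zero."""
    if d_sss < 0 or d_wss < 0:
        raise ValueError("divergences must be non-negative")
    if d_wss == 0:
        return float("nan")
    return d_sss / d_wss


def divergence_table(data: ExpressionData, sex: str, genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-gene d_WSS, d_SSS and ratio over one sex's replicate-line samples."""
    if data.values is None:
        raise ValueError("expression values not populated; call normalize() first")
    wss = data.samples_for(sex, "WSS")
    sss = data.samples_for(sex, "SSS")
    if len(wss) < 2 or len(sss) < 2:
        raise ValueError(f"need >=2 replicate lines per regime for sex {sex!r}")
    values = data.values if genes is None else data.values.loc[list(genes)]
    w = values[wss].to_numpy(dtype=float)
    s = values[sss].to_numpy(dtype=float)
    d_w = np.mean(np.abs(w - w.mean(axis=1, keepdims=True)), axis=1)
    d_s = np.mean(np.abs(s - s.mean(axis=1, keepdims=True)), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d_w > 0, d_s / d_w, np.nan)
    return pd.DataFrame(
        {"gene_id": values.index, "d_WSS": d_w, "d_SSS": d_s, "ratio": ratio}
    ).set_index("gene_id")


def bootstrap_median_summary(
    ratios: Sequence[float],
    n_boot: int,
    alpha: float,
    rng: np.random.Generator,
) -> BootstrapSummary:
    """Mean of bootstrap medians plus BCa interval of the median.

    Genes are the resampling unit; bias-correction comes from the bootstrap
    CDF and acceleration from a gene-level jackknife.
    """
    return bca_summary(np.asarray(ratios, dtype=float), np.median, n_boot, alpha, rng)


def set_vs_background_tests(
    set_ratios: Sequence[float],
    background_ratios: Sequence[float],
    alpha: float = 0.05,
) -> tuple[float, float, float, bool]:
    """KS D and p, one-sided MW U p (set stochastically greater), and
    whether the MW result is reported under the KS-significance gate.

    Both raw statistics are always computed; the gate only marks whether the
    MW p-value would be quoted.
    """
    a = np.asarray(set_ratios, dtype=float)
    b = np.asarray(background_ratios, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both the set and the background must be nonempty")
    ks = stats.ks_2samp(a, b)
    mw = stats.mannwhitneyu(a, b, alternative="greater")
    return float(ks.statistic), float(ks.pvalue), float(mw.pvalue), bool(ks.pvalue < alpha)


def ortholog_best_hit_filter(hits: pd.DataFrame, min_identity: float = 90.0) -> dict[str, str]:
    """Best-hit ortholog assignment from tabular homology output.

    Hits below ``min_identity`` percent identity are dropped (>= is kept);
    per query the hit with the lowest e-value wins, ties broken by higher
    bitscore, then lexicographic subject id. Distinct queries may map to the
    same subject.
    """
    if hits.empty:
        return {}
    kept = hits[hits["percent_identity"] >= min_identity]
    mapping: dict[str, str] = {}
    ordered = kept.sort_values(
        ["query_id", "evalue", "bitscore", "subject_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    for query, grp in ordered.groupby("query_id", sort=False):
        mapping[str(query)] = str(grp["subject_id"].iloc[0])
    return mapping


def analyze_expression_divergence(
    data: ExpressionData,
    gene_sets: Mapping[str, tuple[str, Sequence[str]]],
    config: RunConfig | None = None,
    exclude_sets_from_background: bool = False,
) -> DivergenceResult:
    """Full divergence analysis: filter, divergence table per sex, set summaries.

    ``gene_sets`` maps set name to ``(sex, gene ids)``; each set is compared
    against all expressed transcripts of its sex (the background includes
    the set's own genes unless ``exclude_sets_from_background``). When raw
    counts are available, the expressed-transcript filter (cpm strictly
    above ``config.cpm_threshold`` in every sample of the sex) is applied;
    otherwise all genes in the matrix are taken as expressed.
    """
    config = config or RunConfig()
    data = normalize(data, config.normalization if data.values is None else "precomputed")

    sexes = sorted({sex for sex, _ in gene_sets.values()} | set(data.sample_meta["sex"]))
    cpm_mat = None
    if data.raw_counts is not None and data.library_sizes is not None:
        cpm_mat = cpm(data.raw_counts, data.library_sizes)

    per_gene: dict[str, pd.DataFrame] = {}
    expressed: dict[str, list[str]] = {}
    for sex in sexes:
        scope = data.samples_for(sex)
        if not scope:
            continue
        if cpm_mat is not None:
            expressed[sex] = filter_expressed(cpm_mat, scope, config.cpm_threshold)
        else:
            expressed[sex] = list(data.gene_ids)
        per_gene[sex] = divergence_table(data, sex, expressed[sex])

    summaries: list[SetSummary] = []
    rng = config.rng("expdiv-bootstrap")
    for sex in per_gene:
        table = per_gene[sex]
        bg_ratios = table["ratio"].dropna()
        n_undef = int(table["ratio"].isna().sum())
        if n_undef:
            logger.info("%s background: %d gene(s) with zero WSS divergence excluded", sex, n_undef)
        summaries.append(
            SetSummary(
                name="background",
                sex=sex,
                n_genes=len(table),
                n_undefined=n_undef,
                boot=bootstrap_median_summary(bg_ratios, config.n_bootstrap, config.alpha, rng),
            )
        )
    for name, (sex, genes) in gene_sets.items():
        if sex not in per_gene:
            raise ValueError(f"gene set {name!r} targets sex {sex!r} with no samples")
        table = per_gene[sex]
        in_set = table.index.intersection(pd.Index(genes))
        set_ratios = table.loc[in_set, "ratio"].dropna()
        n_undef = len(in_set) - len(set_ratios)
        if len(set_ratios) < 3:
            summaries.append(SetSummary(name=name, sex=sex, n_genes=len(in_set), n_undefined=n_undef, boot=None))
            continue
        bg_index = table.index.difference(in_set) if exclude_sets_from_background else table.index
        bg_ratios = table.loc[bg_index, "ratio"].dropna()
        ks_D, ks_p, mw_p, gated = set_vs_background_tests(set_ratios, bg_ratios, config.alpha)
        summaries.append(
            SetSummary(
                name=name,
                sex=sex,
                n_genes=len(in_set),
                n_undefined=n_undef,
                boot=bootstrap_median_summary(set_ratios, config.n_bootstrap, config.alpha, rng),
                ks_D=ks_D,
                ks_p=ks_p,
                mw_p_one_sided=mw_p,
                mw_reported=gated,
            )
        )
    return DivergenceResult(per_gene=per_gene, per_set=summaries)
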