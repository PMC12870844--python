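"""Synthetic data generators with recorded ground truth.

The three generators emulate the structure of the study designs the
analyses assume — mating populations of five males and five females with
focal-male and all-female scoring, a fully crossed line x line
double-mating design per regime with beta-binomially overdispersed
egg-hatch counts, and a 2 sexes x 2 regimes x n replicate-line expression
matrix in which designated gene sets carry regime-dependent
between-replicate variance. Every generator is deterministic given
(truth, sizes, seed), and a :class:`SyntheticTruth` travels with each
dataset so downstream estimators can be checked by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import REGIMES, substream
from .expdiv import ExpressionData

LINE_NAMES = "ABCDEFGHIJKLMNOP"


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind a simulated dataset.

    ``bateman_slope_by_regime`` is the slope of relative reproductive
    success on absolute mating count; ``mating_rate_by_regime`` the mean
    lifetime mating count; ``interaction_sd_by_regime`` the logit-scale SD
    of the male x female cell effect in the double-mating design;
    ``replicate_sd_by_regime_and_geneset`` maps gene-set name (including
    ``"background"``) to per-regime between-replicate expression SDs.
    """

    bateman_slope_by_regime: dict[str, float] = field(
        default_factory=lambda: {"WSS": 0.3, "SSS": 0.6}
    )
    mating_rate_by_regime: dict[str, float] = field(
        default_factory=lambda: {"WSS": 1.0, "SSS": 2.1}
    )
    interaction_sd_by_regime: dict[str, float] = field(
        default_factory=lambda: {"WSS": np.sqrt(0.222), "SSS": np.sqrt(0.633)}
    )
    line_effect_sd: float = 0.1
    overdispersion_rho: float = 0.15
    replicate_sd_by_regime_and_geneset: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "background": {"WSS": 0.30, "SSS": 0.30},
            "SFP": {"WSS": 0.30, "SSS": 0.33},
            "FRP": {"WSS": 0.30, "SSS": 0.31},
        }
    )
    baseline_p2_by_regime: dict[str, float] = field(
        default_factory=lambda: {"WSS": 0.44, "SSS": 0.61}
    )
    offspring_scale: float = 40.0
    offspring_frailty_cv: float = 0.5

    def __post_init__(self) -> None:
        for r in REGIMES:
            if self.mating_rate_by_regime[r] <= 0:
                raise ValueError("mating rates must be positive")
            if self.interaction_sd_by_regime[r] < 0:
                raise ValueError("interaction SDs must be non-negative")
            if not 0.0 < self.baseline_p2_by_regime[r] < 1.0:
                raise ValueError("baseline P2 must lie in (0, 1)")
        if self.line_effect_sd < 0:
            raise ValueError("line_effect_sd must be non-negative")
        if self.offspring_frailty_cv < 0:
            raise ValueError("offspring_frailty_cv must be non-negative")
        if not 0.0 <= self.overdispersion_rho < 1.0:
            raise ValueError("overdispersion_rho must lie in [0, 1)")
        if "background" not in self.replicate_sd_by_regime_and_geneset:
            raise ValueError("replicate SDs must include a 'background' entry")
        for name, by_regime in self.replicate_sd_by_regime_and_geneset.items():
            for r in REGIMES:
                if by_regime[r] < 0:
                    raise ValueError(f"replicate SD for {name}/{r} must be non-negative")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _line_ids(regime: str, n: int) -> list[str]:
    return [f"{regime}-{LINE_NAMES[i]}" for i in range(n)]


# ---------------------------------------------------------------------------
# mating-population assays


def simulate_mating_assays(
    truth: SyntheticTruth,
    n_populations_per_line: int = 5,
    lines_per_regime: int = 4,
    seed: int = 0,
    n_female_populations_per_line: int | None = None,
) -> pd.DataFrame:
    """Simulate focal-male and all-female mating-population assays.

    Each mating population holds 5 males and 5 females. Male-assay
    populations contribute the single focal male's record; female-assay
    populations contribute all five females. Lifetime mating counts are
    Poisson with the regime's mean rate; reproductive success for maters is
    Poisson around ``offspring_scale * (1 + slope * (matings - mean
    retained matings) + line effect) * frailty``, where the gamma frailty
    (CV ``offspring_frailty_cv``) carries the individual-quality
    overdispersion real assay data show. The predictor is centred on the
    post-exclusion mean mating count, so on the relative scale the
    expected gradient of reproductive success on absolute mating count
    equals the truth's Bateman slope. Individuals with zero matings have
    zero offspring.
    """
    if n_populations_per_line < 1 or lines_per_regime < 1:
        raise ValueError("population and line counts must be positive")
    if n_female_populations_per_line is None:
        # the study scored about half as many female as male populations
        n_female_populations_per_line = max(1, round(n_populations_per_line / 2))
    rng = substream(seed, "mating-assays")
    rows = []
    for regime in REGIMES:
        rate = truth.mating_rate_by_regime[regime]
        slope = truth.bateman_slope_by_regime[regime]
        # the selection indices are estimated on zero-mating-excluded
        # individuals, so the linear predictor is centred on the mean
        # mating count among maters, E[X | X >= 1] for Poisson X
        mean_retained = rate / (1.0 - np.exp(-rate))
        for line in _line_ids(regime, lines_per_regime):
            line_effect = rng.normal(0.0, truth.line_effect_sd)

            cv = truth.offspring_frailty_cv

            def _offspring(matings: int) -> int:
                if matings == 0:
                    return 0
                mean_rel = max(0.0, 1.0 + slope * (matings - mean_retained) + line_effect)
                if cv > 0:
                    mean_rel *= rng.gamma(1.0 / cv**2, cv**2)
                return int(rng.poisson(truth.offspring_scale * mean_rel))

            for p in range(n_populations_per_line):
                pop = f"{line}-M{p}"
                matings = int(rng.poisson(rate))
                rows.append(
                    {
                        "individual_id": f"{pop}-focal",
                        "sex": "male",
                        "line_id": line,
                        "regime": regime,
                        "mating_population_id": pop,
                        "matings": matings,
                        "offspring": _offspring(matings),
                    }
                )
            for p in range(n_female_populations_per_line):
                pop = f"{line}-F{p}"
                for j in range(5):
                    matings = int(rng.poisson(rate))
                    rows.append(
                        {
                            "individual_id": f"{pop}-f{j}",
                            "sex": "female",
                            "line_id": line,
                            "regime": regime,
                            "mating_population_id": pop,
                            "matings": matings,
                            "offspring": _offspring(matings),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# double-mating sperm-competition assays


def _draw_eggs(spec, rng: np.random.Generator, size: int) -> np.ndarray:
    """Eggs-per-female distribution spec: ('poisson', mean), an int, or callable."""
    if callable(spec):
        eggs = np.asarray(spec(rng, size), dtype=int)
    elif isinstance(spec, int):
        eggs = np.full(size, spec, dtype=int)
    elif isinstance(spec, tuple) and len(spec) == 2 and spec[0] == "poisson":
        eggs = rng.poisson(float(spec[1]), size=size)
    else:
        raise ValueError(f"invalid eggs-per-female distribution spec: {spec!r}")
    if (eggs < 0).any():
        raise ValueError("eggs-per-female spec produced negative counts")
    return np.maximum(eggs, 1)


def simulate_double_matings(
    truth: SyntheticTruth,
    lines_per_regime: int = 4,
    n_females_per_cell: int = 7,
    eggs_per_female=("poisson", 40),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the fully crossed double-mating design for both regimes.

    Every (female line, male line) cell within a regime is present with
    ``n_females_per_cell`` females. The cell's hatch probability is
    ``logit^-1(logit(baseline P2) + male-line + female-line + cell
    effect)`` with the cell (interaction) effect drawn once per cell from
    ``N(0, interaction_sd^2)``; hatched counts are beta-binomial with
    intra-cell correlation ``overdispersion_rho``.
    """
    if lines_per_regime < 1 or n_females_per_cell < 1:
        raise ValueError("line and female counts must be positive")
    rng = substream(seed, "double-matings")
    rho = truth.overdispersion_rho
    rows = []
    for regime in REGIMES:
        lines = _line_ids(regime, lines_per_regime)
        base = logit(truth.baseline_p2_by_regime[regime])
        int_sd = truth.interaction_sd_by_regime[regime]
        a = {m: rng.normal(0.0, truth.line_effect_sd) for m in lines}
        b = {f: rng.normal(0.0, truth.line_effect_sd) for f in lines}
        for f_line in lines:
            for m_line in lines:
                c = rng.normal(0.0, int_sd) if int_sd > 0 else 0.0
                p_cell = float(expit(base + a[m_line] + b[f_line] + c))
                eggs = _draw_eggs(eggs_per_female, rng, n_females_per_cell)
                if rho > 0:
                    alpha = p_cell * (1.0 - rho) / rho
                    beta = (1.0 - p_cell) * (1.0 - rho) / rho
                    p_female = rng.beta(alpha, beta, size=n_females_per_cell)
                else:
                    p_female = np.full(n_females_per_cell, p_cell)
                hatched = rng.binomial(eggs, p_female)
                for i in range(n_females_per_cell):
                    rows.append(
                        {
                            "female_id": f"{regime}-{f_line[-1]}x{m_line[-1]}-{i}",
                            "regime": regime,
                            "female_line": f_line,
                            "male_line": m_line,
                            "eggs_total": int(eggs[i]),
                            "hatched": int(hatched[i]),
                            "first_mating_ok": True,
                            "second_mating_ok": True,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression matrices


def simulate_expression(
    truth: SyntheticTruth,
    n_genes: int = 20000,
    geneset_spec: Mapping[str, int | Sequence[int]] | None = None,
    n_lines_per_regime: int = 4,
    seed: int = 0,
    counts: bool = False,
    baseline_mean: float = 6.0,
    baseline_sd: float = 2.0,
) -> tuple[ExpressionData, dict[str, list[str]], SyntheticTruth]:
    """Simulate a 2 sexes x 2 regimes x n replicate-line expression matrix.

    Genes are assigned to the named sets in ``geneset_spec`` (name -> gene
    count, or name -> explicit gene indices; assignments must not overlap);
    the rest are background. The value of gene g in the sample of a given
    (sex, regime, line) is ``baseline_g + N(0, sd(regime, set(g))^2)``,
    drawn independently per sample, so the expected divergence ratio of a
    set equals its SSS:WSS SD ratio (mean absolute deviation of a normal
    scales with sigma). With ``counts=True`` a count-scale matrix is
    emitted instead (negative-binomial around ``2^value``), for
    end-to-end runs through the cpm/log normalization path.
    """
    geneset_spec = dict(geneset_spec or {})
    rng = substream(seed, "expression")
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    membership = np.full(n_genes, "background", dtype=object)
    cursor = 0
    gene_sets: dict[str, list[str]] = {}
    for name, spec in geneset_spec.items():
        if isinstance(spec, int):
            idx = np.arange(cursor, cursor + spec)
            cursor += spec
        else:
            idx = np.asarray(list(spec), dtype=int)
        if idx.size and idx.max() >= n_genes:
            raise ValueError(f"gene set {name!r} exceeds n_genes")
        if (membership[idx] != "background").any():
            raise ValueError(f"gene set {name!r} overlaps another set")
        membership[idx] = name
        gene_sets[name] = [gene_ids[i] for i in idx]

    sds = truth.replicate_sd_by_regime_and_geneset
    for name in gene_sets:
        if name not in sds:
            raise ValueError(f"truth has no replicate SDs for gene set {name!r}")

    samples = []
    meta_rows = []
    for sex in ("female", "male"):
        for regime in REGIMES:
            for line in _line_ids(regime, n_lines_per_regime):
                sample = f"{sex[0].upper()}_{line}"
                samples.append(sample)
                meta_rows.append({"sample": sample, "sex": sex, "regime": regime, "line": line})
    meta = pd.DataFrame(meta_rows).set_index("sample")

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    sd_by_regime = {
        regime: np.array([sds[membership[g]][regime] for g in range(n_genes)])
        for regime in REGIMES
    }
    values = np.empty((n_genes, len(samples)))
    for j, sample in enumerate(samples):
        regime = meta.loc[sample, "regime"]
        values[:, j] = baseline + rng.normal(0.0, 1.0, size=n_genes) * sd_by_regime[regime]
    mat = pd.DataFrame(values, index=gene_ids, columns=samples)

    if counts:
        mean_counts = np.maximum(2.0**mat.to_numpy(), 1e-8)
        shape = 20.0  # negative-binomial size parameter: mild extra-Poisson noise
        lam = rng.gamma(shape, mean_counts / shape)
        raw = pd.DataFrame(rng.poisson(lam), index=gene_ids, columns=samples)
        data = ExpressionData(
            values=None,
            sample_meta=meta,
            raw_counts=raw.astype(float),
            library_sizes=raw.sum(axis=0).astype(float),
        )
    else:
        data = ExpressionData(values=mat, sample_meta=meta)
    return data, gene_sets, truth
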