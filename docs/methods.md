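# Methods

This note documents the statistical models behind each pipeline, the
synthetic-data generator that stands in for real assay and sequencing data,
the numerical choices, and the limitations a user should know about.

## Notation and design

Two experimental-evolution regimes: **WSS** (weak sexual selection —
enforced early, largely monandrous reproduction) and **SSS** (strong sexual
selection — lifelong polyandry with sperm competition), each with several
(canonically 4) replicate lines. All analyses treat the regime as the unit
of comparison and the replicate lines as the source of (co)variation.

## Sexual-selection indices (`sexsel`)

Inputs: one row per individual with lifetime mating count `x` and lifetime
reproductive success `o`, plus sex, line and regime labels. Individuals with
`x = 0` (and therefore `o = 0`) are excluded before estimation: their zeros
are known without error and including them biases gradient estimates
toward the origin. Relative measures divide by the sex × regime mean by
default; relativizing per mating population is available
(`relativize_by="population"`) and is meaningful for the female assays,
where each population contributes five individuals.

* **I_s** = sample variance (n − 1 divisor) of relative mating success.
  The divisor is a convention choice; with assay sizes of 30–100 the
  difference from the n divisor is well under the sampling error. A
  nonparametric bootstrap over individuals (percentile/BCa machinery
  below) supplies its CI.
* **beta_B**: REML linear mixed model `relative o ~ 1 + x` with a random
  intercept per line — i.e. lines within a regime share a common gradient.
  No random slope is fitted (few lines; the common-gradient assumption is
  the point of the model). With one line, or when the estimated line
  variance is exactly zero, the fit falls back to OLS, whose slope and SE
  are the limiting case.
* **beta_ss**: plain OLS of relative `o` on relative `x`; **s'_max** =
  sqrt(I_s) × beta_ss.
* **Equality of gradients**: Z = (b1 − b2)/sqrt(se1² + se2²) against the
  standard normal, two-sided.

**Known limitation (important).** The Wald interval of `beta_B` is
conditional on the relativization: dividing by the *realized* sample mean
makes the estimate a ratio `b_raw / mean(o)`, and the denominator's
sampling variance adds a component ≈ b²·Var(x)·Var(rel o)/n that the
model SE cannot see. For shallow gradients this is negligible; for steep
gradients (b ≳ 0.3 on the relative scale with Var(x) ≈ 1.5–2) the Wald
interval undercovers by several points no matter the sample size, with a
delta-method ceiling near 91% for b = 0.4. Treat the SE as a
within-dataset precision measure, not a basis for exact 95% coverage when
the gradient is steep. (Heteroscedasticity of integer offspring noise adds
a further small share; HC-robust SEs recover only part of the gap.)

## Sperm competition (`spermcomp`)

Inputs: one row per doubly-mated female with egg and hatched counts and
female/male line labels; the first male is sterile, so P2 = hatched/eggs.
Females are retained only when two ejaculates demonstrably competed: both
matings occurred, at least one egg was laid, and at least one egg hatched
(P2 = 0 means the focal male transferred no effective ejaculate).

**Per-regime crossed GLM.** Binomial-denominator logit GLM with sequential
(type-I) terms male line, female line, male × female, in that order
(configurable). Dispersion φ = Pearson χ²/residual df of the full model;
term F = (Δdeviance/Δdf)/φ on (Δdf, residual df). Sequential deviances are
exactly additive: they sum with the residual deviance to the null deviance
(asserted in tests). η² of the interaction = its deviance over the total
(all terms + residual); η² definitions vary — this one is the deviance
analogue of SS-based η². The predicted mean P2 averages the cell linear
predictors and back-transforms, with a delta-method CI from the φ-scaled
coefficient covariance. Cells whose pooled hatch proportion reaches 0 or 1
put the cell predictor at ±∞; the fit proceeds and the mean-P2 summary
clips the predictor at ±10 with a warning.

**Route 1 — GLMM variance component.** Penalized quasi-likelihood with the
dispersion *fixed* at the quasi-binomial estimate: iterate the working
response z = η + (y − mμ)/(mμ(1−μ)) with weights w = mμ(1−μ), and fit a
weighted REML linear mixed model with independent random effects for male
line, female line and their interaction (intercept-only fixed part,
residual variance fixed at φ/w). The inner REML is a direct 3-parameter
optimization of the restricted likelihood (statsmodels' MixedLM does not
take observation weights); it reproduces MixedLM exactly in the unweighted
case (tested). The SE of the interaction component comes from the
numerical Hessian of the restricted likelihood at the optimum. The whole
procedure is deterministic. *Limitation:* like all PQL-type algorithms, it
attenuates variance components when the dispersion is large — with φ ≈ 7
(strong within-cell overdispersion) and a 4×4 design, simulation shows
~30% downward bias. The moments estimator
(`interaction_variance_component_moments`) — interaction mean square of
continuity-corrected cell empirical logits minus the φ-scaled binomial
sampling variance — does not attenuate and is reported alongside as the
robustness check; its SE is the cruder normal-theory sqrt(2/df)·MS.

**Route 2 — arcsine-root ANOVA ratio.** y = arcsin√P2 weighted by egg
count; sequential weighted two-way ANOVA per regime. The interaction share
is its percentage of the total weighted SS; the between-regime test is
F = MS_int(SSS)/MS_int(WSS) on the two interaction dfs, one-sided for the
directional prediction (interaction stronger under SSS); the two-sided
value is also reported.

**Route 3 — residual cell-mean bootstrap.** Fit the additive (no
interaction) GLM per regime; residual = hatched − eggs·fitted p; average
residuals per design cell; the statistic is the sample variance of the 16
cell means — the deviation from additivity in offspring units. Females are
resampled with replacement *within their cells* (preserving the crossed
design; the resampling unit is a design choice — cell-level resampling
would mix the quantity being measured into the resampling noise). BCa
intervals use bias-correction from the bootstrap CDF and acceleration from
a delete-one-female jackknife. Between regimes: variance-ratio F on
(cells−1, cells−1) df, one-sided, and Bartlett's test on the two groups of
cell means (wrapped to return χ² = 0, p = 1 when every group is constant,
where the textbook formula degenerates).

**Within- vs between-line crosses.** One-sided rank-sum (within > between)
per regime and pooled; exact enumeration when both groups have ≤ 20
observations, normal approximation with tie correction otherwise.

## Expression divergence (`expdiv`)

Inputs: a normalized gene × sample matrix (or raw counts + library sizes)
with one sample per (sex, regime, line), gene sets, and optionally
12-column tabular homology output. The built-in normalization is
log2(cpm + 0.5); any externally applied variance-stabilizing transform can
be passed through (`normalization="precomputed"`) — the divergence *ratio*
is invariant to per-gene location shifts and global rescaling (asserted as
property tests), so the choice of transform affects results only through
its gene-specific curvature.

* **Expressed-transcript filter**: cpm strictly > 2 (configurable) in
  *every* sample of the relevant sex (8 samples); applied to cpm of raw
  counts, not to normalized values. The per-sex scope is a reading choice;
  per-sex×regime and all-16-sample scopes can be had by passing the
  corresponding sample lists to `filter_expressed`.
* **Divergence**: d = mean_i |x_i − mean(x)| over the (4) replicate-line
  values; ratio = d_SSS/d_WSS, undefined (NaN, excluded and counted) when
  d_WSS = 0.
* **Set summaries**: genes resampled with replacement (default 9,999
  times); reported is the mean of the bootstrap medians with the BCa
  interval of the median. (An alternative reading — a bias-corrected point
  estimate — differs negligibly for these sample sizes; the bootstrap-mean
  convention is implemented.)
* **Set vs background**: two-sample KS (D, asymptotic p), then one-sided
  Mann–Whitney U for "set stochastically greater". Following the gated
  protocol, the MW result is flagged as reportable only when KS rejects,
  but both raw values are always computed and stored. The background
  includes the set's own genes by default (`exclude_sets_from_background`
  to change); at set/background sizes of ~50/18,000 the difference is
  immaterial.
* **Ortholog filter**: drop hits with identity < 90% (≥ kept), then per
  query keep the lowest-e-value hit; ties broken by higher bitscore, then
  lexicographic subject id. Distinct queries may map to one subject
  (no reciprocal-best requirement).

## Synthetic-data generator (`simulate`)

The generator encodes the study conditions as defaults and records every
parameter in a `SyntheticTruth` for recovery testing.

* **Mating assays.** Populations of 5 males + 5 females; five male-assay
  populations per line (one focal male record each) and half as many
  female-assay populations (five female records each), matching the
  study's relative assay effort. Mating counts are ordinary Poisson with
  regime means 1.0 (WSS) and 2.1 (SSS) — the observed regime means; a
  zero-truncated law cannot have mean 1.0, and zero-maters are exactly
  what the exclusion rule removes downstream, so zeros are generated and
  excluded rather than never generated. Offspring of maters are Poisson
  around scale·(1 + b·(x − E[x | x ≥ 1]) + line effect) multiplied by a
  gamma frailty (CV 0.5 by default): the frailty carries the
  individual-quality overdispersion that real lifetime-fitness data always
  show — pure Poisson noise at these means would make the Bateman
  regression nearly deterministic (R² ≈ 0.9), which no assay resembles.
  Centering on the post-exclusion mean mating count makes the truth's `b`
  exactly the relative-scale gradient the estimator targets.
* **Double matings.** Fully crossed per regime; cell hatch probability
  logit⁻¹(logit(P2 baseline) + male-line + female-line + cell effect),
  the cell effect drawn once per cell from N(0, interaction variance);
  female-level counts are beta-binomial with intra-class correlation ρ
  (default 0.15, chosen so the implied dispersion 1 + (m̄−1)ρ ≈ 7 matches
  the magnitude seen in such assays); eggs per female follow a
  user-supplied spec (default Poisson(40), floored at 1) since the
  source data do not pin this distribution down. Default baselines 0.44
  (WSS) and 0.61 (SSS); default interaction variances 0.222 and 0.633.
* **Expression.** One sample per (sex, regime, line); value = gene
  baseline (N(6, 2²), a log2-expression-like scale) + N(0, sd(regime,
  set)²) drawn independently per sample. Because the mean absolute
  deviation of a normal is proportional to σ, a set's expected divergence
  ratio equals its SSS:WSS SD ratio — the lever every recovery test uses.
  A count-scale mode (gamma-Poisson around 2^value, then cpm + log)
  exercises the normalization path end to end.

**What the generator does not emulate:** mating-sequence dynamics and male
sterility mechanics (hatch failure is taken as paternity truth);
mean–variance trends across expression levels, gene–gene correlation, and
batch structure in RNA-seq; line effects shared between the assay types.
Passing recovery tests therefore demonstrates estimator correctness under
the assumed structure, not robustness to everything real data can do.

## Determinism and problem sizes

All randomness flows from one seed through named, crc32-keyed substreams
(`RunConfig.rng("stage")`), so adding a stage never perturbs another
stage's draws and equal configurations give byte-identical outputs. The
test suite's simulation studies use deliberately economical sizes chosen
for stable Monte-Carlo behavior: 200 replicates for size/coverage/recovery
checks (3-SE bands around nominal rates), a 6×6×8 crossed design with
ρ = 0 for interaction-variance recovery (isolating the component from
overdispersion attenuation), and 1,000–10,000-gene matrices for the
expression properties. The acceptance script runs the study-scale designs
with the full 9,999 bootstrap resamples.
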