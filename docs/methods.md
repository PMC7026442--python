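# Methods

This note documents the models and procedures implemented in `expolink`, the
assumptions behind them, the tunable parameters with their defaults, and the
limitations of the synthetic test surface.

## Cross-study normalization

Expression matrices are assumed to arrive on a log2-like scale, one study at
a time, with a case/control label per sample. Each gene row is standardized
across *all* samples of its study:

    Z_ij = (g_ij − mean(g_i)) / SD(g_i)

- **SD convention.** Sample standard deviation (n−1 denominator). This makes
  the transform exactly idempotent and gives output rows unit sample SD; the
  test suite pins the convention.
- **Degenerate rows.** Genes with zero SD or any missing value are dropped
  from that study and recorded on the returned object, never silently set to
  zero (a zero row would masquerade as a perfectly null gene). No imputation.
- **Probe collapsing.** Microarray probe rows map to gene symbols through a
  user-supplied two-column map; one probe is retained per symbol by policy
  (`max_mean` default, `max_abs_t`, or `first`). Symbols are upper-cased so
  sets intersect across platforms.

## Differential expression

Per gene, an unpaired two-sided t-test compares cases with controls.

- **Variant.** Welch (unequal variances) is the default; the pooled-variance
  Student test is available by flag. Welch is the safer default when the two
  arms come from different tissue sources with different dispersions.
- **Where each statistic is computed.** The t statistic is computed on the
  Z-normalized matrix (it is invariant to the per-gene affine transform, so
  this is a presentation choice, not a numerical one); log fold change
  `logFC = mean(case) − mean(control)` is computed on the pre-normalization
  log2 matrix, because Z-scores have no fold-change units.
- **Selection rule.** A gene is *up* when `p* ≤ 0.01` and `logFC ≥ 1`,
  *down* when `p* ≤ 0.01` and `logFC ≤ −1`, where `p*` is the BH-adjusted
  p-value by default. A raw-p mode is retained because both readings of the
  threshold are defensible; the output table always records t, raw p,
  adjusted p, logFC and the assigned direction, so either rule can be
  re-applied downstream.
- **BH adjustment** is the standard step-up procedure (one shared
  implementation, also used by the enrichment module), monotone in rank and
  capped at 1.

## Diseasome construction

For each direction (up, down) independently — the two networks are never
merged — a bipartite graph is built, centered on the exposure:

- Gene nodes are exactly `∪_d (G_exposure ∩ G_d)`: genes dysregulated in the
  exposure *and* at least one disease, in the same direction.
  Disease-private DE genes stay in the per-study gene-set files but do not
  enter the graph.
- Disease–disease association records exist when `n_ij = N(G_i ∩ G_j) ≥ 1`;
  exposure–disease records are always emitted. Each record carries the
  shared count and the Jaccard coefficient
  `E(i,j) = N(G_i ∩ G_j)/N(G_i ∪ G_j)`, computed over the two significant
  sets as written — no genome-background denominator.
- Exports (GraphML, SIF, edge-list TSV) order nodes lexicographically so the
  bytes are reproducible.

## Enrichment

Over-representation of a query set against each term of a GMT library uses
the one-sided (greater) Fisher exact test on the 2×2 table
(overlap / query-only / term-only / neither). The background universe
defaults to the union of all genes in the library and can be overridden;
p-values are BH-adjusted within one library (not across libraries). Only the
Fisher p is computed — no combined/permutation scores — and the full ranked
table is reported; shortlisting is a presentation choice (`top_k`), with no
attempt to reproduce any particular published shortlist.

## Survival analysis

- **Stratification.** A patient is *altered* for a gene when the tumor
  expression z-score satisfies `|z| ≥ z*`; default `z* = 2.0`, the common
  portal convention for calling expression alteration. Configurable.
- **Kaplan–Meier.** Product-limit estimate over distinct event times; at
  tied times deaths precede censorings (everyone with `time ≥ t_j` is at
  risk at `t_j`); censored-only times create no step but deplete later risk
  sets.
- **Log-rank.** Two-group statistic `(Σ(O−E))² / ΣV` with the hypergeometric
  variance including the `(n_j−d_j)/(n_j−1)` tie factor, referred to χ²(1).
  With no tied event times it coincides exactly with the Cox score test for
  a single binary covariate (cross-checked in the tests).
- **Cox proportional hazards.** The partial likelihood is maximized by
  Newton–Raphson with step-halving on likelihood decrease; convergence when
  the score sup-norm < 1e−8 (or the step < 1e−10), max 100 iterations.
  Ties: Efron by default (better with month-resolution data), Breslow
  available. Standard errors from the inverse observed information; Wald
  two-sided p-values; `HR = exp(β)` exactly. Coefficients diverging beyond
  |β| > 15 raise a monotone-likelihood (separation) error rather than
  returning a spurious fit; non-convergence is flagged, never silent.
- **Screen layout.** Per candidate gene, three model blocks mirror the
  conventional reporting format: *univariate* (gene status alone),
  *multivariate* (all candidate genes of the cohort jointly, gene covariates
  only), *combined* (one gene plus the clinical factors). The combined model
  is fitted for every screened gene, with a `logrank_selected` flag
  recording which genes the altered-vs-normal log-rank test selects at the
  chosen α — this keeps the report complete while preserving the
  log-rank-gated reading of the combined model. Genes are flagged when the
  univariate Wald p ≤ α (default 0.05); KM curve pairs are emitted for
  flagged genes.
- **Clinical covariates.** Categorical factors are dummy-encoded against the
  most frequent level; single-level factors are dropped with a warning;
  patients with missing time/event are excluded listwise with a logged
  count. The factor list is whatever the run config declares — no fixed
  number of factors is assumed.

## Synthetic data: what it emulates and what it does not

The generators provide a ground-truth test surface standing in for public
expression studies and clinical cohorts.

- **Expression.** Gene baselines ~ U(6, 12) on the log2 scale with i.i.d.
  Gaussian noise (default SD 0.5, a typical residual spread for log2
  microarray intensities); planted genes shift cases by ±`effect_size`
  (default 2 log2 units), so the expected case−control difference *is* the
  log fold change. Linked-study generation plants chosen genes as shared
  between the exposure and each disease (with a few genes shared to several
  diseases) plus disease-private genes drawn outside the exposure signature,
  and records the planted overlap counts as ground truth.
- **Survival.** Event times are exponential with hazard
  `h_i = exp(βᵀx_i)/scale` (default scale 60 months); censoring times are an
  independent exponential whose rate is solved numerically so the expected
  censored fraction hits `censor_rate` (default 0.3). Alteration status is
  Bernoulli per gene (default rate 0.25); a z-score matrix consistent with
  the planted status at the cohort's threshold is emitted alongside, so the
  stratification path is exercised end to end. Clinical factors are drawn
  independently of gene status, giving a clean null for combined-model
  calibration.
- **Demo conditions.** The full demo uses a 3000-gene universe, 20 case +
  20 control samples per study, effect 2, noise 0.5; it plants 392/511
  up/down exposure genes, per-cancer DE totals of 939, 553, 890 and 691, and
  exposure-shared overlaps of 36, 13, 25 and 17 (up/down splits 20/16, 8/5,
  15/10, 10/7). At these settings a planted gene sits ≈12 SE from the null,
  so the thresholds recover the planted counts essentially exactly; survival
  cohorts use n = 250 with β = ln 2 planted on two genes each. A `small`
  scale (400 genes, 12/12 arms, n = 120) with proportionally smaller planted
  sets exists for fast smoke runs. Simulation sizes elsewhere (100-seed Cox
  recovery at n = 500, 1000-seed log-rank calibration at n = 200) were
  chosen as the smallest sizes at which the asymptotic properties under test
  are expected to hold cleanly.
- **Not emulated.** Probe-level artifacts, batch/platform effects, missing
  values, correlated genes, non-proportional hazards, informative censoring,
  competing risks. Passing tests therefore demonstrate correctness of the
  statistics and the plumbing under the stated models — not robustness to
  the messiness of real microarray or registry data.

## Numerical and design choices

- Sub-stream seeds are derived deterministically from one global integer
  seed per study/cohort, and all derived seeds stay below 2³¹.
- Both empty sets make the Jaccard score an error, not 0 or NaN.
- Floating outputs are serialized at fixed precision (`%.10g` matrices,
  `%.6g` reports), so a rerun with the same config and seed is
  byte-identical; the run manifest records a SHA-256 per artifact.
- The pipeline aborts on the first failing stage, naming it, and keeps the
  partial outputs listed in the manifest.

## Known limitations

- The Cox implementation targets the screen's scale (hundreds of patients,
  tens of covariates); it has no stratified baselines, time-varying
  covariates, robust variance or proportionality diagnostics.
- Enrichment assumes the background contains every observed gene; choosing
  a biologically appropriate background is the user's responsibility.
- The diseasome restricts gene nodes to exposure-shared genes by design;
  disease–disease similarity beyond shared significant genes (e.g.
  correlation of effect sizes) is out of scope.
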