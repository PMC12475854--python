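# Methods

## The enrichment model

A proximity-labeling pull-down compares a bait–ligase fusion against a
freely diffusing cytosolic ligase. Both label and capture thousands of
proteins; the interactome is defined *differentially*. `proxidiff` models
log2 LFQ intensities of each protein group as approximately normal within
a group and asks, per protein, whether the bait group's mean exceeds the
control's.

The stages run in a fixed order — log2 transform, completeness filter,
left-censored imputation, Welch test, fold-change z-scoring, hit calling,
CV QC — because each stage's contract depends on the previous one:
imputation needs the filter to guarantee one nearly complete group, the
z-score population is defined over exactly the proteins that were tested,
and the QC CV deliberately goes back to the *raw, observed* intensities so
that imputation noise cannot flatter reproducibility.

### Completeness filter

A protein is retained iff `valid_bait/n_bait ≥ f` **or**
`valid_ctrl/n_ctrl ≥ f`. OR-semantics are essential: proteins quantified
only in the bait pull-down are the strongest candidates, and demanding
completeness in both groups would delete them. `f` defaults to 1.0
(appropriate at n = 3, where partial evidence is too thin) and 0.75 for
larger designs (e.g. 11 vs 9, where 9/11 ≈ 0.82 still passes). An empty
result is a warning, not an error.

### Left-censored imputation

LFQ missingness is dominated by censoring at the detection limit (MNAR),
so missing values are drawn from a normal placed in the low-abundance tail
of each sample column: mean `μ_c − d·σ_c`, SD `w·σ_c`, with `μ_c`, `σ_c`
the observed column moments. Defaults `w = 0.5, d = 1.6` (and
`w = 0.4, d = 1.7` in the `brain` preset) follow the established
downshifted-normal convention for this data type. Per-column moments are
the default scope because column-wise abundance distributions differ
between runs; a whole-matrix scope is available (`impute_scope="matrix"`).
Draws use one root seed with per-column child streams keyed by a CRC32 of
the column *name*, so reordering columns cannot silently reshuffle the
imputation. A column with fewer than two observed values cannot supply
moments and raises an error naming the column.

### Welch test

Implemented directly (sample variances, Welch–Satterthwaite df, two-sided
p from the t distribution) rather than delegated, so that scipy's
implementation remains available as an independent cross-check in the test
suite. The degenerate zero-variance-in-both-groups case is defined, not an
error: equal means give (t = 0, p = 1), unequal means give p = 0 with a
`DegenerateVarianceWarning`.

A caution that matters for calibration claims: at n = 3 vs 3 the
Welch–Satterthwaite approximation is *conservative* — its true size at
nominal α = 0.05 is ≈ 0.035–0.04, as the test suite demonstrates against
scipy on simulated null data. This is a property of the test itself, not
of the implementation; power statements at very small n inherit it.

### Fold-change z-score

`z_i = (Δ_i − mean Δ)/SD(Δ)` with the sample SD (n−1), computed by default
over **all** proteins passing the completeness filter
(`z_population="all_filtered"`). Standardizing over the full tested
population is the less biased choice: restricting to p < α first
(`"significant_only"`, provided as a switch) truncates the Δ distribution
and shifts the z reference. By construction mean(z) = 0 and SD(z) = 1 to
numerical tolerance on every run, which the suite asserts at 1e-10.

### Hit calling and QC

`hit ⇔ p < α ∧ z > z_cutoff ∧ Δ > 0` with strict inequalities (boundary
values are not hits). The z cutoff (default 1; 2 for a high-confidence
view) acts as a population-relative effect-size filter that removes
small-Δ proteins whose p-values are driven by tiny variances — this is why
the joint null hit rate sits far below α. The QC statistic is the percent
CV (sample SD / mean × 100) of observed raw-scale bait-group intensities
per hit (never imputed values, which would shrink it), averaged over the
hit set and compared against 30%. A pooled-group CV variant is switchable
(`cv_scope="pooled"`).

### Reported ratio

`ratio = 2^(mean log2 bait − mean log2 control)` — the geometric-mean
ratio, consistent with the pipeline operating on log2 values. An
arithmetic mean-of-ratios is deliberately not offered; it is not the
quantity the test statistics describe.

## Concordance

Two hit tables are compared on gene symbols after collapsing protein-group
isoforms to one entry per gene; rows without a symbol fall back to their
protein-group id so nothing silently disappears. Symbols are trimmed and
upper-cased by default because datasets following different species
capitalization conventions (Bin1 vs BIN1) must match; switchable off.

## Gene-set over-representation

Upper-tail hypergeometric test per term — `P(X ≥ k)` for k hit genes in a
term of K background genes, n hits, N background — with BH step-up FDR
across all tested terms and fold enrichment `(k/n)/(K/N)` as effect size.
The background is always an explicit user-supplied gene universe: hits
outside it are dropped with a warning, term membership is intersected with
it, and K = 0 terms are not tested. One-sided testing only (the upper
hypergeometric tail equals the one-sided Fisher exact test); no GO-DAG
hierarchy handling. Published fold-enrichment values from web services
depend on their private backgrounds and are therefore not reproducible
targets — only the math is.

## Power analysis

For the two-sided two-independent-means design: Cohen's
`d` from (CV, fold change), noncentrality `λ = d√(n/2)`, `df = 2n − 2`,
`power = P(|T'_{df,λ}| > t_{1−α/2,df})` with the exact noncentral t (no
normal approximation — the n of interest is 5–10). Two conventions map
(CV, fc) to d, and the headline claim holds under both:

- `lognormal` (default): σ on the log2 scale is `√ln(1+cv²)/ln2`,
  `d = log2(fc)/σ`. Matches the pipeline, which tests log2 values. At
  n = 6, CV 30%, fc 2, α 0.05: power 0.957.
- `raw`: group means 1 and fc, common SD `cv·(1+fc)/2`,
  `d = (fc−1)/(cv·(1+fc)/2)`. Power 0.933 under the same settings.

`min_n_for_power` inverts by doubling + bisection (power is increasing in
n). A vectorized Monte-Carlo Welch simulation under the lognormal model
(`simulate_power`) serves as the independent check; analytic and simulated
power agree within Monte-Carlo error.

## Synthetic data generator

Emulates the statistical structure of a bait-vs-control LFQ experiment:

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 5000 | typical LFQ depth (~5k quantified proteins) |
| `frac_enriched` | 0.05 | minority of proteins truly bait-proximal |
| `effect_log2` | 2.0 | 4-fold spike; ranges (e.g. 1–5.7 ≈ 2–52-fold) supported |
| `n_bait`, `n_ctrl` | 6, 6 | the group size the power analysis nominates |
| `baseline_mean`, `baseline_sd` | 25, 2 | log2 abundance distribution |
| `rep_sd` | 0.2857 | log2 replicate SD ⇒ 20% CV via `cv = √(exp((s·ln2)²)−1)` |
| `censor_limit`, `censor_scale` | 21.8, 0.8 | logistic MNAR missingness, ~10% of cells |

Each cell's log2 value is baseline + spike (bait columns of enriched
proteins) + N(0, rep_sd²) noise; it goes missing with probability
`logistic((L − value)/s)`, so low-abundance cells are censored
preferentially — the exact pattern the downshifted imputation assumes —
while every protein remains testable. A hard threshold (`censor_mode=
"hard"`) exists for worst-case tests, and `"none"` disables missingness
(used for clean null-calibration studies, where imputation would otherwise
mix two questions: test calibration and imputation behavior). The
censoring midpoint/scale were fixed once by numerically integrating the
logistic missingness over the baseline abundance distribution to land near
10% missing cells.

What the generator does **not** emulate: peptide-level structure and
shared peptides, cross-run normalization artifacts, batch effects,
correlated missingness within a run, heavy-tailed contaminant intensities.
Passing recovery tests therefore demonstrate the pipeline's behavior under
its own model assumptions, not performance guarantees on arbitrary real
data.

## Problem sizes and observed operating characteristics

All studies below are computed live by the test suite and
`scripts/acceptance.py`; none of these numbers is hard-coded.

- Recovery (default scenario, seeds 1–10, pooled): sensitivity ≈ 0.92–0.93,
  empirical FDR < 0.02. The sensitivity loss is mostly the completeness
  filter discarding low-abundance enriched proteins whose control values
  are fully censored — a real trade-off of the f = 1.0 filter, visible
  because the generator's truth is known.
- Null studies (no true effects, n = 3 vs 3): fraction of p < 0.05
  ≈ 0.035 (Welch conservatism, see above); joint p/z/sign hit rate far
  below α.
- Monte-Carlo power cross-check at 5·10⁴ replicates; imputation moment
  checks at 10⁴–10⁵ draws per column.

## Numerical choices and edge cases

- Sample SD (ddof = 1) everywhere: z-scores, CVs, imputation moments,
  Welch variances — small-n estimates.
- Strict inequalities at every cutoff; p or z exactly at the threshold is
  not a hit.
- CV is undefined (NaN, excluded from QC averages) below 2 observed
  values; constant fold-change vectors make the z-score undefined and
  raise rather than divide by zero.
- Imputation determinism: identical (matrix, params, seed) gives bitwise
  identical output; the CLI manifest reproduces runs byte-identically.
- Enrichment tables round-trip through TSV at 12 significant digits.

## Known limitations

- Protein inference, precursor-level quantification, and cross-run
  normalization are upstream concerns; the pipeline consumes a finished
  protein-group matrix.
- The z-score population choice and the CV scope are conventions, not
  identified by any data; both are switchable and documented above.
- Multiple-testing control at the protein level is intentionally the
  joint p/z/sign rule rather than an FDR-adjusted p: the z cutoff
  empirically controls false discoveries in this setting, but no formal
  FDR guarantee is claimed. BH correction is applied where it belongs —
  across gene-set terms.
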