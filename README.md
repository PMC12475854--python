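# proxidiff

Differential enrichment analysis for proximity-labeling proteomics.

Proximity labeling (BioID/TurboID) fuses a promiscuous biotin ligase to a
bait protein so that everything within ~10–20 nm is biotinylated, captured
on streptavidin, and quantified by label-free mass spectrometry. The bait's
interactome is *not* the list of captured proteins — a freely diffusing
cytosolic ligase captures thousands of bystanders too — but the set of
proteins **enriched** in the bait pull-down relative to that spatial
control. `proxidiff` implements the statistical pipeline that turns two
wide protein-group × sample LFQ intensity matrices (bait replicates vs.
control replicates) into a ranked interactome, for proteomics researchers
analyzing DIA-NN / MaxQuant-style protein matrices.

## The model

Per protein group, with log2 LFQ intensities `x` (bait, n₁ replicates) and
`y` (control, n₂ replicates):

1. **Completeness filter** — keep the protein iff it is quantified in at
   least a fraction *f* of the replicates of **one** group (f = 1.0 for
   small designs, 0.75 for larger in vivo designs). One-group semantics
   matter: a protein seen only with the bait is the interesting case.
2. **Left-censored imputation** — LFQ missingness is missing-not-at-random
   (values below detection). Missing cells in sample column *c* are drawn
   from `N(μ_c − d·σ_c, (w·σ_c)²)` where μ_c, σ_c are the column's
   observed mean/SD — a down-shifted (d = 1.6–1.7), narrowed (w = 0.4–0.5)
   normal in the low-abundance tail, the Perseus convention.
3. **Welch's t-test** — `t = (x̄ − ȳ)/√(s₁²/n₁ + s₂²/n₂)` with
   Welch–Satterthwaite df; two-sided p.
4. **Fold-change z-score** — the log2 difference standardized against the
   mean and SD of *all* tested proteins' differences:
   `z_i = (Δ_i − mean Δ)/SD(Δ)`; a population-relative effect-size cutoff.
5. **Hit call** — `p < α` ∧ `z > z_cutoff` ∧ `Δ > 0` (strict inequalities;
   defaults α = 0.05, z > 1).
6. **CV QC** — percent coefficient of variation of the *observed* raw-scale
   bait intensities per hit; the hit-set average must stay below 30%.

Around the core pipeline the package provides gene-level **concordance**
between two interactomes (isoforms collapsed to one gene entry),
**over-representation** of a hit list against user-supplied GMT gene sets
(upper-tail hypergeometric p, Benjamini–Hochberg FDR, fold enrichment
`(k/n)/(K/N)`), the **power analysis** for the two-independent-means design
parameterized by replicate CV and fold change (exact noncentral-t), and a
**synthetic LFQ generator** with ground truth (log-normal abundances,
spiked enrichment, logistic left-censoring) for validation.

## Worked example

```text
$ proxidiff simulate --seed 1 --out matrix.tsv --truth truth.tsv
wrote 5000 proteins x 12 samples to matrix.tsv

$ proxidiff run --matrix matrix.tsv --design design.tsv --bait bait --seed 1 --out-dir results
236 hits of 4110 tested proteins; hit-set average CV 18.3% (passes <30% QC)
```

The simulated matrix has 5000 proteins, 250 of them truly 4-fold enriched
in the bait group, 6 vs 6 replicates at 20% replicate CV and ~10%
left-censored missing cells. 4110 proteins survive the completeness filter;
the joint p/z/sign call flags 236, recovering (per `truth.tsv`) 93% of the
spike-ins at an empirical FDR of 1.3%. Top of `results/enrichment.tsv`:

```text
protein_id     gene  diff_log2    ratio  p_welch        z  cv_bait_pct
     P4467 GENE4467   2.979237 7.885688 0.000488 5.626622    16.131052
     P1331 GENE1331   2.762403 6.785256 0.007908 5.200183    19.698714
     P3650 GENE3650   2.646061 6.259558 0.000629 4.971377    11.811659
```

`ratio = 2^diff_log2` is the geometric-mean bait/control enrichment. The
design question behind such experiments:

```text
$ proxidiff power --n 6 --cv 0.30 --fc 2
n_per_group  cv   fold_change  alpha  convention  power
6            0.3  2            0.05   lognormal   0.9567

$ proxidiff samplesize --power 0.90 --cv 0.30 --fc 2
target_power  cv   fold_change  alpha  convention  min_n  achieved_power
0.9           0.3  2            0.05   lognormal   5      0.9031
```

Six replicates per group comfortably exceed 0.90 power to detect a 2-fold
enrichment at 30% CV. Named pipeline presets `--preset n2a`
(f = 1.0, w = 0.5, d = 1.6) and `--preset brain` (f = 0.75, w = 0.4,
d = 1.7) pin the two standard parameterizations; `proxidiff concord` and
`proxidiff enrich-sets` cover the cross-dataset overlap and gene-set
over-representation steps. Every run writes a JSON manifest that
reproduces its outputs byte-identically.

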