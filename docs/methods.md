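# Methods

## Problem and model

Bulk tumor cohorts routinely come with somatic mutation calls (MAF from
whole-exome sequencing) and bulk RNA-seq on the same samples. The package
identifies, per mutated gene, the tumor-infiltrating cell types whose
abundance pattern is associated with the gene's mutation status — "driven"
cells — and evaluates their prognostic value as a Cox risk signature.

The analysis treats cell abundance as a relative, unitless quantity per
(cell type, sample), produced either by the built-in single-sample GSEA
scorer or by any external deconvolution method. The identification itself
is deliberately abundance-method-agnostic: any cells × samples matrix with
matched sample ids enters the same SAM → z-binarization → Fisher/FDR
cascade.

## Pipeline stages and their assumptions

**Mutation matrix.** A gene–sample cell is 1 if at least one non-silent
variant (nonsense, missense, frame-shift indel, splice site, nonstop,
translation start site, in-frame indel — matched case-insensitively against
the canonical MAF `Variant_Classification` tokens) is recorded. The
mutation frequency denominator is the declared sample universe (the
expression-matched samples), so mutation status is defined for every
analyzed sample; the retention threshold (default 1%) is **inclusive**
(frequency ≥ threshold), so a gene mutated in exactly 1% of samples is
kept. TCGA-style barcodes are matched after truncation to a configurable
prefix (default 15 characters, the TCGA sample level), because DNA and RNA
aliquot barcodes differ in their suffix.

**ssGSEA scoring.** Per sample, genes are ranked by descending expression
(ties broken by ascending gene id for bit-reproducibility); a signature's
score is the sum over all ranking positions of the weighted hit CDF minus
the miss CDF, with rank weight `(N − rank + 1)^alpha`. Defaults:
`alpha = 0.25` and global (max − min) range normalization of the whole
score matrix. The score depends only on within-sample ranks, hence is
invariant to any per-sample monotone transform of expression (this is
asserted by tests). External algorithms (xCell's spillover model,
CIBERSORT's nu-SVR) are intentionally not re-implemented; their exported
matrices import through the same interface.

**SAM.** Two-class unpaired statistic `d = (mean_mut − mean_wt)/(s + s0)`
with the pooled scatter and a fudge factor chosen by the
coefficient-of-variation criterion over s-quantile windows (candidates: 0
and the 0,5,…,100 percentiles of s). Significance uses a pooled permutation
null — all permuted statistics across cells are pooled, per-cell p-values
take the `(1 + count)/(1 + total)` form, and BH converts them to q-values.
With only tens of cell types (rather than thousands of genes) the classic
SAM delta-table has very coarse resolution; the pooled null is the design
choice here, and the permutation engine is isolated so the delta-table
variant could be added. Inside `sam_test` the samples are internally
reordered to a canonical (sorted-id) order before drawing permutations, so
results are invariant under any joint reordering of the inputs, and
bit-reproducible for a fixed seed.

**Binarization.** Dysregulated cells' abundance rows are z-scored across
*all* samples jointly (sample SD, ddof = 1; constant rows become zeros and
are flagged). An entry is an up-response if z > 2 (strict) and a
down-response if z ≤ −2 (inclusive). The threshold 2.0 marks per-sample
*extreme excursions*; a direct consequence, visible in the synthetic
experiments, is that the responding group must be a minority of the cohort
(roughly < 20% of samples) for any entry to clear the threshold — with a
homogeneous shift in a large mutated fraction the row SD inflates and the
ceiling of z drops below 2. This matches the intended reading "extreme
response in a minority of (mutated) samples".

**Exact association.** Each dysregulated cell is tested against the binary
matrix matching its SAM direction only (up matrix if d > 0); testing both
directions would double the comparisons without adding interpretable
calls. The two-sided Fisher exact test uses the minimum-likelihood
convention (all margin-fixed tables whose hypergeometric probability does
not exceed the observed one); the reported odds ratio is the sample odds
ratio ad/bc (∞ when bc = 0 with ad > 0, undefined for degenerate margins,
where p = 1). BH adjustment is applied per gene across its tested cells;
an across-gene global mode is available behind a flag (`global_fdr`).

**Risk signature.** Risk score = ∑ β_k a_k over the driven cells, raw
abundances by default (`zscore=True` switches to row-standardized ones).
β comes from a native Newton–Raphson maximization of the Cox partial
likelihood with Breslow tie handling (Efron available); convergence
requires every score-vector component < 1e-6, at most 100 iterations with
step-halving; covariance is the inverse observed information. Zero-variance
cells are dropped with a warning; collinear columns are detected by a
greedy rank check and later-indexed duplicates dropped. Patients split at
the median score (ties at the median go to the low-risk group, a
deterministic convention); groups are compared by the standard two-group
log-rank test; Kaplan–Meier curves come from lifelines.

## Synthetic cohorts and what passing tests show

The generator emulates the statistical structure the pipeline assumes:

- mutation status per gene: independent Bernoulli at a stated frequency;
- baseline cell abundance: standard normal per cell × sample; planted
  (gene, cell) effects add ±effect (in SD units) to mutated samples;
- survival: exponential times with hazard `h0 · exp(∑ β_c a_c)`
  (h0 = 0.01/day) and independent exponential censoring whose rate is tuned
  to the requested marginal censor fraction (default 30%) at baseline;
- optionally, an expression matrix in which each cell's signature genes
  (10 per cell, from a generated GMT) equal that cell's abundance plus
  Gaussian noise, over a background of 300 unrelated genes — so the full
  expression → scoring → identification path is exercisable.

Default study conditions for the calibration and power experiments are
n = 200 samples, 30 cells, 10 genes; null calibration uses 20% mutation
frequency and no plants; power uses +2 SD plants at 30% frequency. The
gene-dropout robustness experiment runs on the expression path with
10% mutation frequency, +4 SD plants and signature noise SD 3.0: rarer
mutations and noisy signatures are both the realistic regime (most
recurrently mutated genes sit at 1–10% frequency; bulk signature genes
correlate only moderately with cell abundance) and the regime where
rank-based scores retain the extreme-excursion tail that the z > 2
binarization needs. Dropout uses a *nested* removal series (the removed
gene set at 5% is contained in that at 10%, etc., one random order per
seed), a coupling that makes the information removed monotone in the
fraction and sharpens the seed-averaged overlap curve.

What the synthetic experiments do **not** show: performance under
correlated cell types (real abundances are strongly correlated),
non-Gaussian / heavy-tailed abundance distributions (a heavier-tailed noise
option exists but is off by default), batch structure, subclonal mutations,
or miscalibrated deconvolution. Passing the planted-truth tests
demonstrates the machinery is correct and calibrated under its own model,
not that any particular biological call in real data is right.

## Numerical choices

- Fisher exact p-values delegate to scipy's implementation, which was
  verified exhaustively against a margin-fixed enumeration oracle for all
  tables with margins ≤ 12 (max |Δp| ≈ 3e-16); BH delegates to
  statsmodels. Both sit behind thin package functions so the conventions
  are pinned by tests.
- Permutation p-values use the +1 pseudocount and never reach 0.
- All rank ties break deterministically by ascending identifier.
- `run_all` records a manifest (config, seed, package version, input
  SHA-256 checksums, per-stage content hashes); re-runs skip stages whose
  hash and outputs are intact, and a failing stage leaves a `FAILED` marker
  naming it. Result tables are byte-identical across runs for a fixed seed.
- Problem sizes in the acceptance script (50 seeds for calibration and
  power, 25 for Cox recovery, 10 for the dropout curve) were chosen to
  keep Monte-Carlo standard errors small relative to the margins being
  checked while the whole script stays desk-scale.

## Known limitations

- The SAM FDR is the pooled-permutation/BH variant, not the original
  delta-threshold table; q-values can differ slightly from the classic
  implementation.
- The exact test treats samples as exchangeable; covariates (subtype,
  purity, batch) are not adjusted for.
- The z > 2 response definition is insensitive to mutations carried by a
  large fraction of the cohort when the response is homogeneous (see
  above); such effects are still detected by SAM but may yield no binary
  response entries, hence no driven-cell call.
- Cell-type abundance estimates from bulk data are relative; risk-score
  coefficients are per abundance unit of the chosen scoring method and not
  transferable across methods without recalibration.
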