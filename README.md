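# mutcell

Identification of **somatic-mutation-driven immune cells** from paired tumor
genomic and bulk transcriptome data.

Somatic mutations in protein-coding regions can generate neoantigens that
trigger an immune cell response in the tumor microenvironment. `mutcell`
asks, for every recurrently mutated gene in a cohort: *which
tumor-infiltrating cell types respond to this mutation?* It integrates two
matrices over a shared set of samples:

- a **binary mutation matrix** `M` (genes × samples, 1 = any non-silent
  mutation), built from a MAF file with the standard non-silent variant
  classes (nonsense, missense, frame-shift indels, splice site, nonstop,
  translation start site, in-frame indels) and a mutation-frequency
  threshold (default 1%, inclusive);
- a **cell-abundance matrix** `A` (cells × samples), inferred from bulk
  expression with a built-in single-sample GSEA scorer, or imported from any
  external deconvolution tool (xCell, CIBERSORT, ...).

## Method

For each mutation gene *g* with binary status vector *m*:

1. **Differential abundance (SAM).** Every cell row of `A` is tested with
   the moderated statistic *d* = (x̄₁ − x̄₀)/(s + s₀), where *s* is the
   pooled two-class scatter and *s₀* a fudge factor chosen by the
   coefficient-of-variation rule. Significance comes from a pooled
   permutation null with Benjamini–Hochberg q-values; cells with q < 0.05
   are "dysregulated" with direction sign(*d*).
2. **Binarization.** Dysregulated cells' rows are z-scored across samples
   and thresholded: an entry is an *up-response* if z > 2 and a
   *down-response* if z ≤ −2, giving two binary response matrices.
3. **Exact association.** For each dysregulated cell, the 2×2 table of
   (mutation status) × (binary response, taken from the matrix matching the
   cell's SAM direction) is tested with the two-sided Fisher exact test;
   p-values are BH-adjusted across the cells tested for that gene, and
   cells with FDR < 0.05 are reported as **driven** by the mutation.
4. **Risk signature.** For a chosen gene, the driven cells *S* define a
   per-patient risk score ∑_{k∈S} β_k a_k, with β_k from a multivariate Cox
   proportional-hazards fit (Breslow ties, Newton–Raphson) of overall
   survival on the abundances. Patients are split at the median score and
   the high/low-risk groups compared with the log-rank test and
   Kaplan–Meier curves.

Mutation waterfall (oncoprint), co-occurrence/mutual-exclusivity, abundance
heat-map and KM plots are provided; each plot also writes the exact layout
table it was drawn from.

## Worked example

The package ships a synthetic-cohort generator with known ground truth.
Here three gene→cell effects are planted (+2 SD abundance shifts in mutated
samples for `G001→C003` and `G004→C008`, −2 SD for `G006→C012`) in a cohort
of 200 samples, 30 cell types and 10 mutation genes, and `C003` additionally
drives hazard (β = 0.8):

```python
import mutcell as mc

truth = mc.make_truth(
    10, 30,
    planted=[(0, 2, 1, 2.0), (3, 7, 1, 2.0), (5, 11, -1, 2.0)],
    frequency=0.3,
    survival_betas={"C003": 0.8},
    seed=42,
)
cohort = mc.generate_cohort(200, 30, 10, truth)

model = mc.MutationImmuneModel(cohort.abundance, cohort.mutations, cohort.survival)
results = model.fit(n_perm=1000, seed=7)
print(results.summary())
```

```
gene cells  cell_count  mutation_rate
G001  C003           1          0.300
G004  C008           1          0.315
G006  C012           1          0.280
```

All three planted pairs are recovered, and nothing else. The per-gene
detail table carries the exact-test evidence (`results.detail("G001")`):

```
cell direction  odds_ratio        p      fdr
C003        up         inf 0.002154 0.002154
```

The infinite odds ratio says every sample with an extreme `C003` excursion
carries a `G001` mutation. The Cox risk signature on `G001`'s driven cells
recovers the planted hazard effect and separates the median-split groups:

```python
risk = results.risk_model("G001").fit()
print(risk.summary())          # beta=0.944, HR=2.57 for C003 (truth beta=0.8)
print(risk.logrank_p)          # 6.4e-22
```

The same pipeline runs from files on disk (MAF + expression TSV + GMT +
survival TSV) through `MutationImmuneModel.from_files` or the CLI:

```sh
mutcell simulate --n 200 --cells 30 --genes 10 --plant G001:C003:+:2.0 \
    --freq 0.3 --seed 42 --out sim/
mutcell run --cells sim/abundance.tsv --mut sim/mutation_matrix.tsv \
    --surv sim/survival.tsv --nperm 1000 --seed 7 --out run/
```

which writes `summary.tsv`, per-gene `detail/*.tsv`, the plots with their
layout tables, the risk-group assignments, and a run manifest with input
checksums for reproducibility.

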