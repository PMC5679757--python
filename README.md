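# rintx

RNA-quality-aware analysis of bulk brain RNA-seq for aging and dementia
cohorts.

Postmortem RNA integrity (RIN) is systematically lower in donors who died
with dementia, and a large share of the transcriptome covaries with RIN.
A naive dementia-vs-control differential expression analysis therefore
confuses degradation genes with disease genes.  `rintx` provides the full
chain needed to expose and remove that confound, plus a seeded synthetic
cohort generator that plants it, so every claim is testable against
ground truth:

- **TbT total-signal normalization** in linear FPKM space, conserving the
  data set's total log2(FPKM + 1) to relative 1e-9.
- **Mixture-aware RIN correction** per gene and region: exclude zeros and
  >3 SD outliers, fit one or two Gaussians (BIC), regress expression on
  (RIN, RIN²) within each component, keep residual + component mean.
  Modeling the mixture first preserves genuine bimodality (sex-linked
  genes) while removing the degradation trend.
- **Differential expression** by gene-wise linear models with optional
  surrogate variables, fold-change/significance gene counting, per-gene
  RIN association, corrected-vs-uncorrected rank concordance, greedy
  RIN/sex-matched subcohorts, and permutation distance-matrix regression
  (MDMR) for variance explained.
- **Signed co-expression modules**: soft-power adjacency, topological
  overlap, eigengene merging to a module cap, kME reassignment with an
  unassigned module 0, neuronal-marker relabeling, and eigengene-trait
  association.
- **Cross-study gene-list tools**: scaled-rank concordance with exact
  Wilcoxon divergence, cell-type marker sets (2-fold over every other
  type, FPKM > 1), exact hypergeometric enrichment.
- **Cohort statistics**: Welch t-tests from raw data or printed
  (n, mean ± SD) summaries and exact 2×2 hypergeometric tests.

The scientific background and every modeling decision are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Generate the default confounded cohort (106 donors, 5,000 genes), run the
hippocampus through normalization and both DE passes, and compare:

```python
import rintx
from rintx import pipeline

cfg = rintx.SimulationConfig(seed=1)
donors, samples = rintx.generate_cohort(cfg)
matrices, truth = rintx.generate_expression(donors, samples, cfg)

flags = pipeline.cortex_de_flags(matrices)
norm, scale = rintx.tbt_normalize(matrices["HIP"], flags)
corrected, report = rintx.rin_correct_matrix(norm, samples)

meta = samples.set_index("sample_id")
dem = donors.set_index("donor_id")["dementia"]
labels = dem.loc[meta.loc[norm.sample_ids, "donor_id"]].to_numpy()

de_raw = rintx.differential_expression(norm, labels)
de_cor = rintx.differential_expression(corrected, labels)
params = rintx.DEParams(correction="bh")
print("uncorrected up/down:", rintx.count_de_genes(de_raw, params))
print("corrected   up/down:", rintx.count_de_genes(de_cor, params))
print("rank concordance: %.2f" % rintx.ranking_concordance(de_raw, de_cor)[0])
```

```
uncorrected up/down: (163, 336)
corrected   up/down: (19, 21)
rank concordance: 0.70
```

Without RIN correction ~500 genes look dementia-associated at BH 0.05 and
fold > 1.3; after correction only ~40 remain — essentially the planted
disease genes — while the overall fold-change ordering stays strongly
correlated (Spearman ≈ 0.70), i.e. the confound inflates significance far
more than it reorders genes.  The same chain is available from the shell:

```sh
rintx run --out results/demo --seed 1 --genes 5000 --regions HIP
rintx stats welch --n1 50 --m1 6.87 --s1 0.92 --n2 29 --m2 6.18 --s2 1.27
```

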