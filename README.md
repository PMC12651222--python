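# omicstack

Hybrid multi-omics subtype classification informed by protein–protein
interaction (PPI) networks — for computational biologists who want a
leakage-safe, fully reproducible pipeline from three omics matrices to
cross-validated subtype predictions and a ranked biomarker list.

Molecular subtypes of lower-grade glioma (IDHmut-codel, IDHmut-non-codel,
IDHwt) — or any three-class stratification — are predicted from mRNA
expression, miRNA expression and DNA methylation. The method:

1. **Gene-centric integration.** Each miRNA is mapped to its most frequently
   reported target gene; each CpG probe to its (deduplicated) gene set; every
   gene then carries a three-channel vector per patient
   *(mrna, meth, mirna)*, zero-filled where a layer has no measurement.
2. **Shared-topology patient graphs.** A STRING-style scored edge list is
   filtered at combined score ≥ 400, deduplicated (max score wins) and
   restricted to annotated genes. Every patient shares this topology; node
   features are patient-specific.
3. **Two base learners.** A graph attention network (GAT) with per-head
   transforms *h′ = W h*, attention
   *e_ij = LeakyReLU(aᵀ[h′_i ‖ h′_j])*, *α_ij = softmax_j(e_ij)*, and
   ELU-activated weighted sums (*K* heads concatenated, then averaged;
   mean-pool readout) — and a random forest (*T* trees, majority vote
   *ŷ = mode{h_t(x)}*, Gini importance).
4. **ElasticNet feature selection** (per fold): minimise
   *1/(2n)‖y − Xβ‖² + λ[α‖β‖₁ + (1−α)/2·‖β‖²]* with α = 0.1 over a 50-point
   log-spaced λ grid chosen by inner 5-fold CV.
5. **SMOTE balancing** (per fold): minority classes are raised to the
   majority count with synthetic points *x_new = x_i + δ(x_j − x_i)*,
   δ ~ U(0,1), x_j among the k = 5 nearest minority neighbours.
6. **Ridge-logistic stacking.** A multinomial logistic meta-model (the
   3-class extension of *p(y=1|x) = 1/(1+e^−(β₀+β₁x₁+…))*) combines the six
   out-of-fold base-model class probabilities.
7. **Biomarker ranking.** Per-gene forest importance and per-gene incoming
   attention mass Σᵢ α_ij, fold-averaged, min–max scaled and combined
   50/50; each gene annotated with its best omic layer by one-way ANOVA.

Everything runs inside repeated stratified 5-fold cross-validation with all
statistics confined to training folds; an audit object proves it.

A synthetic-cohort generator with planted subtype-discriminative genes,
cross-layer correlation, class imbalance and a scale-free PPI network makes
the whole pipeline testable offline — no downloads.

## Worked example

```python
from omicstack import (CVPlan, HybridStackModel, PipelineConfig,
                       SimulationConfig, generate_cohort)
from omicstack.gat import GATConfig

# 140 patients (60/60/20), 200 genes, 20 planted discriminative genes,
# effect size 2 SD, anti-correlated methylation, hub-placed truth genes
cohort = generate_cohort(SimulationConfig(seed=11))

config = PipelineConfig(
    gat=GATConfig(heads=2, hidden=4, epochs=60, patience=10,
                  dtype="float32", seed=11),   # desk-scale graph model
    inner_folds=3, seed=11,
)
model = HybridStackModel.from_cohort(cohort, config)
results = model.fit(CVPlan(n_folds=5, n_repeats=1, seed=11))

print(results.summary())
print(results.biomarkers().head(5)[["rank", "gene", "combined", "best_omic"]])
```

Output (exact, deterministic for this seed):

```
     model       accuracy      precision         recall             f1        roc_auc          auprc
0       RF  1.000 ± 0.000  1.000 ± 0.000  1.000 ± 0.000  1.000 ± 0.000  1.000 ± 0.000  1.000 ± 0.000
1      GAT  0.279 ± 0.127  0.246 ± 0.101  0.317 ± 0.050  0.198 ± 0.077  0.539 ± 0.107  0.407 ± 0.072
2  Stacked  0.979 ± 0.020  0.985 ± 0.014  0.972 ± 0.034  0.977 ± 0.025  1.000 ± 0.000  1.000 ± 0.000

   rank      gene  combined best_omic
0     1  GENE0167  0.882463    RNASeq
1     2  GENE0087  0.852345    RNASeq
2     3  GENE0162  0.761064    RNASeq
3     4  GENE0091  0.690477    RNASeq
4     5  GENE0029  0.662383    RNASeq
```

Reading it: each cell is mean ± SD over the five folds. The forest separates
the planted signal perfectly; the graph arm is near chance (mean-pooling over
200 nodes dilutes a 20-gene signal — see `docs/methods.md`); the stacked
model learns to trust the informative arm and stays within noise of it. Of
the top-20 combined biomarkers, all 20 are planted truth genes in this run
(`precision@20 = 1.0`), and `best_omic` reports which layer separates the
classes most sharply per gene.

The same run from the shell:

```bash
omicstack simulate --out cohort/ --set seed=11
omicstack run --config run.cfg --out artifacts/   # paths + parameters
omicstack rank --artifacts artifacts/ --weight 1.0 --top 20
```

`artifacts/` then contains `fold_results.tsv`, `summary.tsv`, `ttests.tsv`
(paired t-tests of the stack against each base model), `anova.tsv`,
`biomarkers.tsv`, `selected_features.tsv`, `audit.tsv` and a `manifest.json`
carrying the config hash — re-running the same configuration reproduces
every table byte for byte.

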