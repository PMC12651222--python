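# Methods

`omicstack` classifies cancer samples into molecular subtypes from three
omics layers — mRNA expression, miRNA expression, DNA methylation — by
combining two complementary views of the same gene-centric data: a random
forest over the selected feature values, and a graph attention network (GAT)
over a shared protein–protein interaction (PPI) topology in which each gene
is a node carrying that patient's three channel values. A ridge-penalised
multinomial logistic regression stacks the two models' class probabilities.
The motivating application is the three-subtype stratification of
lower-grade glioma (IDH-mutant with/without 1p/19q co-deletion, and
IDH-wildtype, a rare class), but nothing in the code is specific to it.

## Gene-centric integration

All three layers are reduced to one gene universe:

* miRNA identifiers are canonicalised (lowercase; `-3p`/`-5p` arm tags and
  `.N` variant tags stripped repeatedly, so the rule is idempotent) and each
  miRNA is assigned the target gene with the highest summed report count in
  the interaction table. Ties break to the lexicographically smallest gene
  symbol — every resolution rule in this package is deterministic by
  construction.
* CpG probes carry semicolon-joined gene lists; these are split, uppercased
  and deduplicated preserving first-seen order.
* Per gene and sample the three channels are (expression, mean beta over
  mapped probes, mean expression over mapped miRNAs), zero where a layer has
  no measurement for that gene. The mean is our reducer; the most-variable-
  probe alternative was considered and rejected as less stable on small
  cohorts.

## PPI graphs

Edges with a combined confidence score below 400/1000 are dropped; symmetric
duplicates collapse to one undirected edge keeping the **maximum** score;
self-loops in the input and edges touching genes absent from the annotated
data are removed. Node order is frozen lexicographically. Genes left without
any edge are excluded from the topology by default (attention over a
degree-0 node is undefined without self-loops); a flag retains them. Every
patient shares this topology; only the node-feature matrix
(genes × channels) differs.

## The attention model

Two attention layers. Per head, node features are linearly transformed
(`h' = W h`), pairwise logits `e_ij = LeakyReLU(a·[h'_i ‖ h'_j])` (slope
0.2) are softmax-normalised over each node's neighbourhood (self-loops
included so a node never discards its own signal), and the new
representation is the attention-weighted sum of the transformed neighbours
followed by an ELU. The hidden layer concatenates its K heads; the output
layer averages them; graph-level readout is the mean over nodes followed by
an affine softmax classifier.

Defaults follow common practice for this architecture: 8 heads, 64 hidden
channels, dropout 0.5 (inputs, hidden features and attention weights),
learning rate 1e-3, decoupled weight decay 1e-4. Training is full-batch
Adam — the whole cohort fits in memory, and dropout supplies the gradient
noise — with early stopping on a 10 % stratified validation split (patience
20, best weights restored). Because the topology is shared, forward and
backward passes are vectorised across patients with segment operations over
a destination-sorted edge list; gradients are derived by hand and verified
against finite differences. A deliberately slow loop-based implementation of
the same equations (`omicstack.reference`) is kept as an independent oracle.

**Known behaviour of the mean-pool readout.** Averaging node embeddings over
hundreds of genes dilutes class signal that lives in a small subset of
nodes; on the synthetic cohorts below the GAT arm alone performs near
chance, and the stacked model's accuracy is carried by the forest arm. The
stacking meta-learner is expected to handle exactly this asymmetry (it
learns to downweight the weaker probability block), and the attention scores
remain informative for ranking because incoming attention mass concentrates
on network hubs. We kept the canonical readout rather than a per-node
(flattened) readout, which would tie the parameter count to the node count.

## Feature selection

ElasticNet with mixing parameter 0.1 and 50 log-spaced penalties in
[1e-5, 1]. Class labels enter as a one-hot multi-response target; since the
penalty is separable, each response column is fitted independently by cyclic
coordinate descent on the Gram matrix (convergence: max coefficient change
< 1e-6; each coordinate update is an exact minimisation, so the objective is
non-increasing within sweeps — asserted in tests). The penalty is chosen by
stratified 5-fold CV minimising held-out squared error, ties resolving to
the larger (sparser) penalty. The selected support is the union over
responses of coefficients with |β| > 1e-8; an empty support falls back to
the largest penalty with any non-zero coefficient, and as a last resort the
single most label-correlated column, so selection is never empty.

## Class balancing

SMOTE with k = 5 minority neighbours (Euclidean), run **after** selection and
standardisation in the low-dimensional selected space, equalising every
class to the majority count. Each synthetic sample records its parent pair
and interpolation weight; the identical interpolation is re-applied to the
full standardised feature row so the forest and the graph model train on the
same augmented cohort. Classes with fewer neighbours than k reduce k
silently (logged); a singleton class is an error.

## Cross-validation and leakage control

Repeated stratified 5-fold CV (3 repeats by default). Within each training
fold, in order: variance filter (training variance < 1e-12), per-feature
z-scoring, ElasticNet selection, SMOTE, model fits; test rows only ever pass
through frozen transforms. Stacking meta-features are out-of-fold: the
training fold is split again (stratified; 5 inner folds by default) and the
entire base pipeline is refit per inner fold, so no meta-training row is
predicted by a fit that saw it. An audit object records the sample set
behind every fitted statistic and aborts the run on any overlap with the
fold's test rows; a deliberate whole-dataset standardisation switch exists
solely to prove the audit catches it.

Metrics per fold: accuracy, macro-averaged precision/recall/F1, and
one-vs-rest macro ROC-AUC and AUPRC (classes absent from a test fold are
excluded from the AUC macro with a warning). Macro averaging treats the rare
subtype symmetrically. Model comparisons use a paired two-sided t-test over
the repeat × fold cells, with explicit degenerate branches (identical
vectors → t=0, p=1; constant non-zero differences → ±∞, p→0).

## Biomarker ranking

Per fold, forest impurity importances are summed over each gene's selected
channels, and GAT attention scores are the per-gene incoming attention mass
Σ_i α_ij averaged over patients, layers and heads, excluding self-loop mass
(self-attention reflects the architecture, not biology; a flag includes it).
Both components are averaged over folds, min–max scaled to [0, 1], and
combined as `w·RF + (1−w)·attention` with w = 0.5 (w = 1 and w = 0 recover
the single-component views). Ties rank lexicographically. Each gene is
annotated with its most discriminative omic layer by one-way ANOVA against
the subtype labels (smallest p wins; all-zero channels are skipped). For
Figure-style displays, values are min–max normalised to [0, 1], with a
constant vector mapping to 0.5 by convention.

## Synthetic cohorts

The generator emulates a post-differential-analysis cohort and is the test
bed for every claim above:

* Three classes sized (60, 60, 20) by default — the third class mirrors the
  underrepresentation of the IDH-wildtype subtype.
* 200 genes, of which 20 "informative" genes receive a class-conditional
  mean shift of `effect_size` (default 2.0) in units of the unit
  within-class SD; the shifted class cycles over the three subtypes so each
  is covered. All other features are exchangeable Gaussian noise.
* Methylation betas are a logistic squash of a latent variable correlated
  with the (standardised) mRNA value of the probe's first mapped gene at
  `cross_layer_rho` (default −0.5: hypermethylation tracks low expression,
  the epigenetic-silencing direction). The squash attenuates the Pearson
  correlation slightly; the achieved value stays within ±0.15 of the target
  at n ≥ 100.
* miRNAs whose resolved target is informative couple to that gene's value at
  |cross_layer_rho|; the first informative genes are used as designated
  top-reported targets so the miRNA channel carries signal.
* The PPI network is preferential attachment (2-node seed graph with one
  edge; each new gene attaches to `min(m, existing)` distinct genes drawn by
  degree), giving 1 + Σ min(m, k) edges; with `hub_informative` (default)
  informative genes are added first and therefore become hubs, so
  attention-based hub recovery is testable. Edge scores are uniform integers
  in [400, 1000].
* One integer seed drives everything; identical configurations export
  byte-identical files.

What the generator does **not** emulate: count-distributed reads, batch
effects, probe-level artefacts, copy number, survival. Passing tests
demonstrate internal correctness and recoverability of planted structure,
not clinical performance on real cohorts.

## Problem sizes used in the shipped experiments

The cross-validated experiments in the test suite and in
`scripts/acceptance.py` run on the default cohort (140 samples, 200 genes,
~400 network edges) with a narrower graph model (2 heads, 4 hidden channels,
≤60 epochs, float32) and 3 stacking inner folds — the package's own choice
of a desk-scale configuration; all preprocessing, balancing and stacking
logic is identical to the defaults. Null-calibration runs use 5-fold × 3
repeats; signal-recovery runs use 5-fold × 1 repeat per seed across three
seeds; the dose–response check uses a 70-sample, 60-gene cohort over effect
sizes {0, 0.5, 1, 2}.

## Numerical choices and degenerate inputs

* Coordinate descent: warm starts along the descending penalty path;
  zero-variance columns are forced to zero coefficients; Gram-based updates
  maintain `G·β` incrementally.
* Softmax attention is computed with per-segment max subtraction; attention
  rows sum to 1 within 1e-6 at every layer/head/node (asserted).
* Vote-fraction probabilities from the forest resolve argmax ties to the
  lexicographically smallest class, as do stacked predictions.
* min–max of a constant vector is 0.5 everywhere; paired t-tests on
  zero-variance differences return the documented degenerate values.
* Float32 is available for the graph model's heavy runs; the default is
  float64, and the dense-oracle agreement is asserted in float64.

## Limitations

* The GAT readout issue described above: graph-level mean pooling is a weak
  classifier when discriminative genes are few; the hybrid relies on the
  forest arm, which matches the method's own comparative results.
* ElasticNet multi-response handling (one-hot + union of supports) is one of
  several defensible encodings of a 3-class label into a squared-error
  selector.
* SMOTE after selection (not before) is a documented ordering choice;
  nearest neighbours in the full feature space would be dominated by noise
  dimensions.
* The live PPI-database client is implemented but untested by design; all
  tests and examples use local edge tables.
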