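# Methods

## Problem and scope

`pesuscept` implements a two-arm assessment of preeclampsia susceptibility:

1. **Expression arm** — classify early preeclampsia (diagnosed before 34
   weeks) against normal pregnancy from whole-blood expression of the
   IL-4/IL-13 signaling pathway (111 genes), using either a spectral graph
   convolutional network (GCNN) on the pathway protein–protein interaction
   (PPI) graph or a multilayer perceptron (MLP).
2. **Genotype arm** — case-control contingency statistics for the IL-13
   variants rs2069740 (T/A) and rs34255686 (C/A): genotype, allele, and
   two-SNP-combination tests, risk-marker r×c tests within patients, and
   Hardy–Weinberg QC.

The two arms are fused into one susceptibility score by a naive-Bayes rule.
Raw microarray processing (background correction, probe summarization) is
out of scope: the pipeline starts from a normalized log2 gene-by-sample
matrix, with a quantile-normalization operation standing in for the
across-array step of RMA-style pipelines.

## Expression preprocessing

* **Sample filtering** removes labeled groups (e.g. a preterm-birth arm),
  preserving sample order.
* **Quantile normalization** maps every sample (column) onto the
  across-sample mean of order statistics; ties within a column receive the
  mean of their tied reference quantiles. Idempotence is exact for
  continuous data; with ties, columns whose tie patterns differ can drift
  by tie-averaging, which is the standard behavior of this dialect.
* **Batch correction** fits, per gene, the additive means model
  `expression ~ group + batch` by least squares with sum-to-zero batch
  coding (the `removeBatchEffect`-style adjustment) and subtracts only the
  fitted batch terms. The subtracted terms are centered to their
  sample-weighted mean, so the per-gene grand mean is preserved exactly
  even when batches are unbalanced. Group structure is preserved by default
  (`preserve_groups=True`); a batch perfectly aliased with a group is an
  error rather than a silent absorption of the biological signal.
* **Pathway extraction** restricts the matrix to the gene set, in gene-set
  order, reporting members missing from the matrix.

## The pathway graph and spectral convolution

The PPI network is an undirected simple graph read from a SNAP-dialect CSV
(one `entrez,entrez` pair per line). Inducing it onto the pathway keeps
**all** pathway genes as nodes — genes absent from the network become
isolated nodes — because the classifier's input vector must have one entry
per pathway gene.

The operator underlying filtering is the symmetric normalized Laplacian
`L = I − D^(−1/2) A D^(−1/2)` (spectrum in [0, 2]; all-zero rows for
isolated nodes), rescaled to `L̃ = 2L/λ_max − I`. λ_max is computed exactly
by dense eigensolve — free at pathway scale (hundreds of nodes); the bound
λ_max := 2 is available as an opt-in shortcut. An edgeless graph yields
`L̃ = −I` by convention, with a warning.

A Chebyshev filter of order K applies `y = Σ_{k<K} θ_k T_k(L̃) x` with
`T_0 = I`, `T_1 = L̃`, `T_k = 2 L̃ T_{k−1} − T_{k−2}`, evaluated by the
recurrence on the signal (inside training, the K basis matrices of the
fixed graph are precomputed once per level — never per sample). Filters are
K-hop localized.

**Coarsening and pooling.** Graph max-pooling is implemented as in the
ChebNet construction: Graclus-style greedy matching — visit nodes in a
seeded random order, pair each unmarked node with the unmarked neighbor
maximizing `w_ij (1/d_i + 1/d_j)`, ties broken by lowest index — produces
one level of clusters of size ≤ 2; coarse edge weights sum inter-cluster
weight (intra-cluster weight is discarded). After the requested number of
levels, fake degree-0 nodes pad every parent to exactly two children, so
each level is exactly twice the size of the next and siblings occupy
adjacent slots; size-2 1-D max pooling on the permuted signal then equals
per-cluster graph pooling. Fake slots carry 0, which is neutral because
pooling always follows a ReLU. Two levels are built by default, matching
the two convolution/pooling stages.

## Classifiers

Both are scikit-learn-style estimators trained with Adam on softmax
cross-entropy, implemented in NumPy with explicit backpropagation, fully
deterministic given `random_state` (Glorot-uniform init, seeded shuffling).

* **ChebNetClassifier**: [Chebyshev conv (32 filters, K=20) → ReLU →
  max-pool 2] × 2 → flatten → FC 512 → ReLU → FC 128 → ReLU → FC 2 →
  softmax. One scalar input channel per gene.
* **PathwayMLPClassifier**: input 111 → ReLU layers of 42, 21, 10 → 2-unit
  softmax head; 5,849 trainable parameters at default widths.

Training protocol (the study specifies architecture but not optimization):
learning rate 1e-3, batch size 32, up to 200 epochs with early stop when
the epoch training loss fails to improve by `tol=1e-4` for `patience=10`
epochs, stratified 80/20 train/test split, unweighted loss by default (a
`class_weight="balanced"` option exists for the 66-vs-314 imbalance).
Features are standardized on the training split by default — raw log2
intensities sit far from zero, and centering is conventional for
gradient-trained nets. Metrics are accuracy and support-weighted F1
(classes with no true and no predicted members contribute F1 = 0).

## Association statistics

Tests are Pearson chi-square on labeled contingency tables, p-values from
the upper tail of the chi-square distribution at `(r−1)(c−1)` degrees of
freedom, reported at full precision. The correction policy is:

* genotype (2×3) and allele (2×2) main tests: **uncorrected**;
* two-SNP combination carrier tables (2×2): **Yates** continuity
  correction exactly when some observed cell is zero, computed as
  `(max(|O−E|−0.5, 0))² / E` so no cell contribution goes negative;
  uncorrected otherwise.

This split policy is the single inference made about the original
analysis's software behavior, and it is what reproduces every published
p-value from the published counts. Empty rows/columns are dropped with a
warning; a table left with fewer than two informative rows or columns is an
error. No multiple-testing adjustment is applied (none was applied in the
source analysis).

Allele counts are always derived from genotype counts
(`count(X) = 2·hom_X + het`), which conserves chromosomes and resolves the
internal inconsistency of the published rs34255686 allele rows (their group
assignment conflicts with the genotype rows; the chi-square statistic is
unaffected, the direction of effect follows the genotypes).

Odds ratios use `(ad)/(bc)` with the Haldane–Anscombe +0.5 correction when
any cell is zero and a Woolf logit 95% CI; a fully zero row or column is
not estimable. The Hardy–Weinberg QC test is a df=1 goodness-of-fit against
expectations from the sample allele frequency; both groups of the packaged
study counts fail it grossly at both SNPs, which is surfaced as a QC
warning and not interpreted further.

## Evidence fusion

The combined score is naive-Bayes on the odds scale: posterior odds =
classifier odds × Π per-SNP likelihood ratios, where each LR is the
Haldane-smoothed (+0.5 per genotype cell) case/control frequency ratio of
the subject's genotype. The rule assumes the two arms are independent given
disease status; it is monotone in every input, commutative and associative
over the LR list, and returns exactly 0.5 under fully neutral evidence. It
is a modeling extension — the source analysis proposes combining the arms
but defines no rule — and is not calibrated against clinical outcomes.

## Synthetic data

The generators produce data with the structure the analysis assumes, at
desk scale:

* **Graph**: preferential attachment from a single seed edge (path on
  max(2, m) nodes), giving a connected scale-free-style network; node ids
  are synthetic integers with no biological meaning.
* **Expression**: per-gene baselines ~ N(7, 1) log2 units; the
  case-vs-control mean shift is confined to the pathway genes and
  constructed in the span of the `smoothness_rank` (default 10)
  lowest-frequency eigenvectors of the pathway subgraph's normalized
  Laplacian, scaled to Euclidean norm `effect_size` — a graph-smooth
  signal, i.e. exactly the structure a localized spectral filter is built
  to exploit, honoring the hypothesis that pathway connectivity is
  informative. Additive batch offsets are drawn per (gene, batch) ~
  N(0, batch_sd²) with batch assignment independent of class (so batch and
  group are never confounded), plus i.i.d. N(0, noise_sd²) noise.
  Defaults mirror the emulated study design: 66 cases vs 314 controls, 32
  batches, 111 pathway genes inside a 2,000-gene universe (a scaled-down
  stand-in for a full array; only the pathway subset feeds the
  classifiers), noise_sd 1.0, batch_sd 0.5 (batch effects are documented as
  mild in the emulated data), effect_size 8.0 by default — the true effect
  magnitude is unknown, so this is a free simulation knob, not an estimate.
* **Genotypes**: controls drawn from Hardy–Weinberg proportions at the
  control risk-allele frequency; case genotype probabilities are the
  control ones tilted by `OR^(risk-allele count)` and renormalized — the
  standard multiplicative per-allele odds model. Defaults: 150 cases, 150
  controls. No linkage disequilibrium between SNPs is simulated.

What the synthetic data does **not** emulate: probe-level microarray
structure, heavy-tailed or gene-correlated noise outside the constructed
shift, batch–group imbalance, genotyping error, or population
stratification. Passing tests therefore demonstrate correctness of the
algorithms and calibration of the statistics under the stated generative
model, not clinical performance on real cohorts; the published ~83%/82%
accuracies of the emulated study require its actual microarray data and an
unstated train/test protocol and are deliberately not reproduction targets.

## Numerical and design choices

* Exact λ_max by dense eigensolve (graphs here are ≤ a few hundred nodes).
* Graclus visit order is seeded; ties in the matching score break to the
  lowest node index — coarsening is order-dependent, so determinism
  requires a fixed rule.
* Evaluation problem sizes: signal-recovery and calibration runs use the
  default 380-sample generator with a 400-gene universe, reduced epoch
  budgets (60 for the MLP, 25 with patience 5 for the GCNN — both
  sufficient for convergence at these sizes), and 20 seeds for
  null-calibration averages; the chi-square type-I rate uses 1,000
  simulated 150+150 cohorts.
* Under the null (effect 0), both unregularized networks overfit noise and
  score slightly **below** the majority rate on held-out data; the
  calibration check asserts the mean held-out accuracy stays within the
  95% binomial band of a majority-class predictor on one test set.
* Degenerate inputs: single-sample quantile normalization and single-batch
  correction are warnings/no-ops; an all-zero contingency row is dropped
  with a warning; a monomorphic SNP makes HWE and OR non-estimable flags
  rather than exceptions.

## Known limitations

* The GCNN gains no accuracy over the MLP on the synthetic task at default
  sizes — both saturate; the generator was not tuned to separate them.
* The fusion rule's independence assumption is untested on real data, and
  the likelihood ratios inherit any bias in the packaged study counts
  (including their Hardy–Weinberg violations, which may indicate
  genotyping artifacts).
* Combined-genotype carrier tests treat each combination separately
  (marginal 2×2 tables), as in the emulated analysis; they are not a joint
  haplotype model.
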