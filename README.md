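# pesuscept

Preeclampsia susceptibility assessment from two molecular arms:

1. **Pathway-expression classification.** Early preeclampsia vs normal
   pregnancy is classified from whole-blood expression of the 111-gene
   IL-4/IL-13 signaling pathway, either by a spectral **graph
   convolutional network** (Chebyshev polynomial filters on the pathway
   protein–protein interaction graph, with Graclus coarsening and
   binary-tree max pooling) or by a plain **multilayer perceptron**
   (111 → 42 → 21 → 10 → 2).
2. **IL-13 SNP association.** Case-control contingency statistics for
   rs2069740 (T/A) and rs34255686 (C/A): genotype and allele chi-square
   tests, two-SNP genotype-combination carrier tests, clinical risk-marker
   tests within patients, Hardy–Weinberg QC, and odds ratios.

The two arms fuse into one susceptibility score by naive-Bayes: posterior
odds = classifier odds × ∏ per-SNP genotype likelihood ratios.

The package is aimed at computational biologists who want a tested,
offline-reproducible reimplementation of this analysis: a synthetic-data
module generates expression matrices with *graph-smooth* class effects
(mean shifts in the span of low-frequency Laplacian eigenvectors of the
pathway subgraph), scale-free PPI-style graphs, and case-control genotypes
under a multiplicative per-allele odds model, so every stage runs with no
downloads.

## The core models

**Spectral graph convolution.** On the pathway graph with normalized
Laplacian L = I − D^(−1/2) A D^(−1/2), rescaled to L̃ = 2L/λ_max − I, a
filter of order K applies

    y = Σ_{k=0}^{K−1} θ_k T_k(L̃) x,   T_0 = I, T_1 = L̃,
    T_k = 2 L̃ T_{k−1} − T_{k−2},

which is K-hop localized. The network stacks two such layers (32 filters,
K = 20), each followed by ReLU and size-2 graph max pooling on a Graclus
coarsening hierarchy, then dense layers of 512 and 128 units and a 2-class
softmax. Both classifiers are scikit-learn-style estimators
(`fit`/`predict`/`predict_proba`) trained with Adam on cross-entropy,
implemented in NumPy, deterministic given `random_state`.

**Association tests.** Pearson chi-square on labeled tables; the
genotype/allele main tests are uncorrected, and 2×2 carrier tables for
genotype combinations apply the Yates continuity correction exactly when a
cell is zero — the policy that reproduces every published p-value of the
reference cohort from its published counts (packaged in
`pesuscept.study_counts`).

## Worked example

```python
import numpy as np
from pesuscept import (
    ChebNetClassifier, ExprSimConfig, GeneSet, extract_pathway,
    generate_expression_dataset, generate_ppi_graph, induce_pathway_subgraph,
    train, genotype_likelihood_ratio, combine,
)
from pesuscept import study_counts as sc

# synthetic universe: 400-gene scale-free graph, first 111 genes = pathway
graph = generate_ppi_graph(n_genes=400, m_attach=2, seed=1)
pathway = GeneSet("il4_il13", graph.node_ids[:111])

# 66 cases vs 314 controls, graph-smooth class effect of norm 12 log2 units
cfg = ExprSimConfig(effect_size=12.0, seed=7)
ds = generate_expression_dataset(cfg, graph)
expr, _ = extract_pathway(ds, pathway)

clf = ChebNetClassifier(graph=induce_pathway_subgraph(graph, pathway),
                        max_epochs=25, random_state=0)
result = train(clf, expr.values.T, expr.groups, seed=0)
print(f"GCNN test accuracy   {result.test_metrics.accuracy:.4f}")
print(f"GCNN weighted F1     {result.test_metrics.f1_weighted:.4f}")

# fuse an 0.80 expression posterior with the subject's genotypes,
# using the packaged reference cohort counts
lr1 = genotype_likelihood_ratio("TT", sc.RS2069740)
lr2 = genotype_likelihood_ratio("AA", sc.RS34255686)
risk = combine(0.80, [lr1, lr2])
print(f"LR(rs2069740=TT)     {lr1:.3f}")
print(f"LR(rs34255686=AA)    {lr2:.3f}")
print(f"combined posterior   {risk.combined_posterior:.3f}")
```

Output:

```
GCNN test accuracy   1.0000
GCNN weighted F1     1.0000
LR(rs2069740=TT)     1.081
LR(rs34255686=AA)    0.226
combined posterior   0.494
```

The strong simulated pathway effect is fully recovered on the held-out 20%
split. The genotype evidence then shifts the 0.80 expression posterior:
being a TT homozygote at rs2069740 is slightly enriched among cases
(LR ≈ 1.08), but AA at rs34255686 is depleted among cases in the reference
counts (LR ≈ 0.23), pulling the combined posterior down to 0.49.

A command-line interface covers the same pipeline
(`pe-suscept simulate-graph | simulate-expression | simulate-genotypes |
build-graph | train | assoc | combine | report`); every subcommand that
draws random numbers requires `--seed`.

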