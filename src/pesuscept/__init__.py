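"""pesuscept: preeclampsia susceptibility from pathway expression and IL-13
genotypes.

Two analysis arms and their fusion:

1. classify early preeclampsia vs normal pregnancy from IL-4/IL-13 pathway
   gene expression, with either a Chebyshev-filter graph convolutional
   network on the pathway PPI graph or a multilayer perceptron;
2. case-control association statistics for the IL-13 SNPs rs2069740 (T/A)
   and rs34255686 (C/A), plus Hardy-Weinberg QC;
3. a naive-Bayes combination of the classifier posterior with per-SNP
   genotype likelihood ratios.

A synthetic-data module generates expression matrices with graph-smooth
class effects, scale-free interaction graphs and case-control genotypes so
the whole pipeline is testable offline.
"""

from .association import (
    AssociationResult,
    GenotypeCounts,
    OddsRatioResult,
    allele_association,
    allele_counts,
    carrier_test,
    chi_square,
    combined_genotype_association,
    genotype_association,
    genotype_counts_from_records,
    hwe_test,
    odds_ratio,
    risk_marker_association,
)
from .classifiers import (
    ChebNetClassifier,
    Metrics,
    PathwayMLPClassifier,
    TrainResult,
    chebyshev_filter,
    evaluate,
    gcnn_forward,
    mlp_forward,
    train,
)
from .datasets import (
    ExpressionDataset,
    GeneSet,
    read_expression,
    read_gene_set,
    read_genotypes,
    write_expression,
    write_genotypes,
)
from .fusion import RiskAssessment, combine, genotype_likelihood_ratio
from .graph import (
    CoarseningHierarchy,
    PPIGraph,
    ScaledLaplacian,
    coarsen,
    induce_pathway_subgraph,
    normalized_laplacian,
    parse_edge_list,
    permute_signal,
    scale_laplacian,
    write_edge_list,
)
from .preprocess import (
    BatchEffectRemover,
    QuantileNormalizer,
    extract_pathway,
    filter_samples,
    quantile_normalize,
    remove_batch_effects,
)
from .simulate import (
    ExprSimConfig,
    GenoSimConfig,
    SnpModel,
    generate_expression_dataset,
    generate_genotype_dataset,
    generate_ppi_graph,
)

__version__ = "0.1.0"
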