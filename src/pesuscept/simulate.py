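"""Synthetic data generators: PPI-style graphs, pathway expression datasets
and case-control SNP genotypes.

These generators produce data with the statistical structure the analysis
assumes, at desk scale, so every downstream stage is testable without any
download:

* a connected scale-free-style interaction graph grown by preferential
  attachment (synthetic integer "Entrez" ids with no biological meaning);
* a log2 expression matrix over a gene universe containing a connected
  pathway of (by default) 111 genes, with the case/control mean shift
  constructed in the span of the lowest-frequency eigenvectors of the
  pathway subgraph's normalized Laplacian — i.e. a graph-smooth class
  effect, the structure a spectral graph filter is built to exploit —
  plus additive per-(gene, batch) offsets and i.i.d. Gaussian noise;
* subject-level genotypes for biallelic SNPs: controls drawn from
  Hardy-Weinberg proportions at the control risk-allele frequency, cases
  from those proportions tilted by a multiplicative per-allele odds ratio.

Default sample sizes mirror the study design this package reproduces:
66 cases vs 314 controls in 32 batches for expression, 150 + 150 for
genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .datasets import ExpressionDataset
from .graph import PPIGraph, induce_pathway_subgraph, normalized_laplacian
from .datasets import GeneSet

__all__ = [
    "ExprSimConfig",
    "SnpModel",
    "GenoSimConfig",
    "generate_ppi_graph",
    "generate_expression_dataset",
    "generate_genotype_dataset",
]

_ID_OFFSET = 1_000_001  # synthetic integer ids; no accession semantics


@dataclass(frozen=True)
class ExprSimConfig:
    """Configuration of the expression simulator.

    Parameters (all log2 units where applicable)
    --------------------------------------------
    n_genes_total : total genes in the universe (default 2000, a scaled-down
        stand-in for a full array's ~33k probes — only the pathway subset
        feeds the classifiers).
    pathway_size : genes in the signal pathway (default 111).
    n_case / n_control : class sizes (defaults 66 / 314).
    n_batches : processing batches (default 32), assigned independently of
        class so batch and group are never confounded by construction.
    effect_size : Euclidean norm of the case-vs-control mean shift over the
        pathway genes (default 8.0; 0 gives an exact null).
    smoothness_rank : number of low-frequency Laplacian eigenvectors of the
        pathway subgraph spanning the class effect (default 10).
    noise_sd : i.i.d. Gaussian noise SD (default 1.0).
    batch_sd : SD of additive per-(gene, batch) offsets (default 0.5).
    """

    n_genes_total: int = 2000
    pathway_size: int = 111
    n_case: int = 66
    n_control: int = 314
    n_batches: int = 32
    effect_size: float = 8.0
    smoothness_rank: int = 10
    noise_sd: float = 1.0
    batch_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.pathway_size > self.n_genes_total:
            raise ValueError("pathway_size must be <= n_genes_total")
        if self.n_batches > self.n_case + self.n_control:
            raise ValueError("more batches than samples")
        for name in ("n_genes_total", "pathway_size", "n_case", "n_control",
                     "n_batches", "smoothness_rank"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_size < 0 or self.batch_sd < 0:
            raise ValueError("effect_size and batch_sd must be >= 0")


@dataclass(frozen=True)
class SnpModel:
    """Generative model of one biallelic SNP.

    ``allele_freq_control`` is the risk-allele frequency in controls;
    ``odds_ratio`` the per-allele multiplicative risk. Genotype strings are
    built from ``ref_allele``/``risk_allele`` (unordered, e.g. "AT").
    """

    snp_id: str
    ref_allele: str
    risk_allele: str
    allele_freq_control: float
    odds_ratio: float = 1.0

    def __post_init__(self):
        if not 0 <= self.allele_freq_control <= 1:
            raise ValueError("allele frequency must lie in [0, 1]")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")

    def genotypes(self):
        r, a = self.ref_allele, self.risk_allele
        return (r + r, r + a, a + a)  # 0, 1, 2 risk alleles

    def control_probs(self) -> np.ndarray:
        q = self.allele_freq_control
        return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])

    def case_probs(self) -> np.ndarray:
        p = self.control_probs() * self.odds_ratio ** np.arange(3)
        return p / p.sum()


@dataclass(frozen=True)
class GenoSimConfig:
    """Configuration of the case-control genotype simulator."""

    snps: tuple
    n_case: int = 150
    n_control: int = 150
    hwe_in_controls: bool = True
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "snps", tuple(self.snps))
        if not self.snps:
            raise ValueError("at least one SNP model required")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("sample sizes must be >= 1")


def generate_ppi_graph(n_genes: int, m_attach: int, seed: int) -> PPIGraph:
    """Grow a connected scale-free-style graph by preferential attachment.

    Growth starts from a path on ``max(2, m_attach)`` nodes and attaches
    each new node to ``m_attach`` existing nodes with degree-proportional
    probability, so ``n_genes=111, m_attach=2`` yields exactly
    1 + 2*(111-2) = 219 edges. Node ids are synthetic integers.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if not 1 <= m_attach < n_genes:
        raise ValueError("m_attach must satisfy 1 <= m_attach < n_genes")
    initial = nx.path_graph(max(2, m_attach))
    G = nx.barabasi_albert_graph(
        n_genes, m_attach, seed=int(seed), initial_graph=initial
    )
    node_ids = [_ID_OFFSET + i for i in range(n_genes)]
    adj = nx.to_numpy_array(G, nodelist=range(n_genes))
    return PPIGraph(node_ids, adj)


def _smooth_class_shift(pathway_graph: PPIGraph, rank: int, norm: float,
                        rng: np.random.Generator) -> np.ndarray:
    """A mean-shift vector of given Euclidean norm in the span of the
    ``rank`` lowest-frequency eigenvectors of the pathway Laplacian."""
    L = normalized_laplacian(pathway_graph)
    _vals, vecs = np.linalg.eigh(L)
    rank = min(rank, vecs.shape[1])
    w = rng.normal(size=rank)
    shift = vecs[:, :rank] @ w
    nrm = np.linalg.norm(shift)
    if nrm == 0:  # pragma: no cover - degenerate draw
        shift = vecs[:, 0]
        nrm = 1.0
    return shift * (norm / nrm)


def generate_expression_dataset(cfg: ExprSimConfig, graph: PPIGraph) -> ExpressionDataset:
    """Simulate a log2 gene-by-sample matrix with a graph-smooth class effect.

    The first ``cfg.pathway_size`` nodes of ``graph`` are the pathway genes;
    the remaining universe genes get fresh synthetic ids. Case samples
    receive the smooth pathway shift; all samples receive per-(gene, batch)
    offsets ~ N(0, batch_sd^2) and N(0, noise_sd^2) noise on top of
    per-gene baselines ~ N(7, 1).
    """
    if graph.n_nodes < cfg.pathway_size:
        raise ValueError(
            f"graph has {graph.n_nodes} nodes but the pathway needs "
            f"{cfg.pathway_size}"
        )
    rng = np.random.default_rng(cfg.seed)
    pathway_ids = graph.node_ids[: cfg.pathway_size]
    sub = induce_pathway_subgraph(graph, GeneSet("pathway", pathway_ids))

    n_extra = cfg.n_genes_total - cfg.pathway_size
    max_graph_id = max(graph.node_ids) if graph.node_ids else _ID_OFFSET
    extra_ids = [max_graph_id + 1 + i for i in range(n_extra)]
    gene_ids = list(pathway_ids) + extra_ids

    n = cfg.n_case + cfg.n_control
    groups = np.array(["case"] * cfg.n_case + ["control"] * cfg.n_control)
    # round-robin assignment then shuffle: every batch non-empty, batch
    # membership independent of group
    batch_idx = np.arange(n) % cfg.n_batches
    rng.shuffle(batch_idx)
    batches = np.array([f"b{j:02d}" for j in batch_idx])

    baseline = rng.normal(7.0, 1.0, size=cfg.n_genes_total)
    values = np.tile(baseline[:, None], (1, n))
    if cfg.effect_size > 0:
        shift = _smooth_class_shift(
            sub, cfg.smoothness_rank, cfg.effect_size, rng
        )
        values[: cfg.pathway_size, groups == "case"] += shift[:, None]
    if cfg.batch_sd > 0:
        offsets = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_genes_total, cfg.n_batches))
        values += offsets[:, batch_idx]
    values += rng.normal(0.0, cfg.noise_sd, size=values.shape)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    return ExpressionDataset(values, gene_ids, sample_ids, groups, batches)


def generate_genotype_dataset(cfg: GenoSimConfig):
    """Simulate subject-level case-control genotype records.

    Controls follow Hardy-Weinberg proportions at the control risk-allele
    frequency (when ``hwe_in_controls``); case genotype probabilities are
    the control ones times ``odds_ratio**risk_allele_count``, renormalized
    (the standard multiplicative per-allele odds model). Returns a pandas
    DataFrame with ``subject_id``, ``status`` and one column per SNP.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_case + cfg.n_control
    records = {
        "subject_id": [f"P{i:04d}" for i in range(n)],
        "status": ["case"] * cfg.n_case + ["control"] * cfg.n_control,
    }
    for snp in cfg.snps:
        labels = snp.genotypes()
        case_g = rng.choice(3, size=cfg.n_case, p=snp.case_probs())
        control_probs = snp.control_probs()
        if not cfg.hwe_in_controls:
            # mild departure: inflate homozygotes at the expense of hets
            control_probs = control_probs * np.array([1.2, 0.6, 1.2])
            control_probs = control_probs / control_probs.sum()
        control_g = rng.choice(3, size=cfg.n_control, p=control_probs)
        records[snp.snp_id] = [labels[g] for g in np.concatenate([case_g, control_g])]
    return pd.DataFrame(records)
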