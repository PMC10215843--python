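"""Pathway-restricted PPI graphs and the coarsening/pooling machinery for
spectral graph convolutions.

A protein-protein interaction network is read from a SNAP-dialect edge list
(one ``entrez,entrez`` pair per line), induced onto the pathway gene set,
and turned into the objects a Chebyshev-filter network needs:

* the symmetric normalized Laplacian ``L = I - D^{-1/2} A D^{-1/2}`` with
  spectrum in [0, 2] (isolated nodes contribute all-zero rows);
* its rescaling ``2 L / lambda_max - I`` with spectrum in [-1, 1];
* a Graclus-style greedy-matching coarsening hierarchy in which fake
  (degree-0) nodes pad every cluster to exactly two children, so that
  graph max-pooling becomes ordinary 1-D pooling of size 2 on a permuted
  signal.

Isolated pathway genes are kept as nodes: the expression feature vector
must carry one entry per pathway gene regardless of connectivity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets import GeneSet

__all__ = [
    "PPIGraph",
    "ScaledLaplacian",
    "CoarseningHierarchy",
    "EdgeListParseError",
    "parse_edge_list",
    "write_edge_list",
    "induce_pathway_subgraph",
    "normalized_laplacian",
    "scale_laplacian",
    "coarsen",
    "permute_signal",
]


class EdgeListParseError(ValueError):
    """A malformed line in a SNAP-dialect edge list."""


@dataclass
class PPIGraph:
    """Undirected weighted graph over identified genes.

    ``adjacency`` is dense, symmetric, with zero diagonal; ``node_ids`` fixes
    the node order that all downstream signals follow.
    """

    node_ids: list
    adjacency: np.ndarray

    def __post_init__(self):
        self.node_ids = list(self.node_ids)
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = len(self.node_ids)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")
        if len(set(self.node_ids)) != n:
            raise ValueError("node ids are not unique")
        if n and not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if n and np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if n and np.any(self.adjacency < 0):
            raise ValueError("edge weights must be non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency)))

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def edges(self):
        """Iterate (id_i, id_j, weight) over the upper triangle."""
        ii, jj = np.nonzero(np.triu(self.adjacency))
        for i, j in zip(ii, jj):
            yield self.node_ids[i], self.node_ids[j], self.adjacency[i, j]


@dataclass(frozen=True)
class ScaledLaplacian:
    """A normalized Laplacian rescaled to spectrum in [-1, 1]."""

    matrix: np.ndarray
    lambda_max: float


def parse_edge_list(path) -> PPIGraph:
    """Parse a SNAP-dialect CSV edge list into an undirected simple graph.

    Duplicate and reversed-duplicate edges collapse to one edge; self-loops
    are dropped with a warning; malformed lines raise
    :class:`EdgeListParseError` with the line number.
    """
    pairs = []
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            tokens = line.split(",")
            if len(tokens) != 2:
                raise EdgeListParseError(
                    f"line {lineno}: expected two comma-separated ids, got {line!r}"
                )
            try:
                a, b = int(tokens[0]), int(tokens[1])
            except ValueError:
                raise EdgeListParseError(
                    f"line {lineno}: non-integer gene id in {line!r}"
                ) from None
            if a == b:
                n_loops += 1
                continue
            pairs.append((a, b))
    if n_loops:
        warnings.warn(f"dropped {n_loops} self-loop(s) from edge list")
    nodes = sorted({x for p in pairs for x in p})
    index = {g: i for i, g in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)))
    for a, b in pairs:
        adj[index[a], index[b]] = 1.0
        adj[index[b], index[a]] = 1.0
    return PPIGraph(nodes, adj)


def write_edge_list(g: PPIGraph, path) -> None:
    with open(path, "w") as fh:
        for a, b, _w in g.edges():
            fh.write(f"{a},{b}\n")


def induce_pathway_subgraph(g: PPIGraph, gs: GeneSet) -> PPIGraph:
    """Induce the PPI graph onto the pathway gene set.

    The result has exactly the gene-set nodes in gene-set order; pathway
    genes absent from the network become isolated nodes (they still carry
    expression features), and only edges with both endpoints in the set
    survive.
    """
    index = {g_id: i for i, g_id in enumerate(g.node_ids)}
    n = len(gs.gene_ids)
    adj = np.zeros((n, n))
    for a, gid_a in enumerate(gs.gene_ids):
        ia = index.get(gid_a)
        if ia is None:
            continue
        for b in range(a + 1, n):
            ib = index.get(gs.gene_ids[b])
            if ib is None:
                continue
            w = g.adjacency[ia, ib]
            adj[a, b] = adj[b, a] = w
    return PPIGraph(list(gs.gene_ids), adj)


def normalized_laplacian(g: PPIGraph) -> np.ndarray:
    """Symmetric normalized Laplacian; isolated nodes give all-zero rows."""
    A = g.adjacency
    d = A.sum(axis=1)
    n = len(d)
    with np.errstate(divide="ignore"):
        dinv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    L = -A * np.outer(dinv, dinv)
    L[np.arange(n), np.arange(n)] = (d > 0).astype(float)
    return L


def scale_laplacian(L: np.ndarray, lambda_max: float | None = None) -> ScaledLaplacian:
    """Rescale a normalized Laplacian to ``2 L / lambda_max - I``.

    ``lambda_max=None`` computes the exact largest eigenvalue by a dense
    eigensolve (cheap for pathway-sized graphs); passing ``2.0`` opts into
    the spectral-bound shortcut. An edgeless graph (``lambda_max == 0``)
    returns ``-I`` with a warning.
    """
    L = np.asarray(L, dtype=float)
    if lambda_max is None:
        lambda_max = float(np.linalg.eigvalsh(L)[-1]) if L.size else 0.0
    if lambda_max <= 1e-12:
        warnings.warn("edgeless graph: scaled Laplacian falls back to -I")
        return ScaledLaplacian(-np.eye(L.shape[0]), 0.0)
    return ScaledLaplacian((2.0 / lambda_max) * L - np.eye(L.shape[0]), lambda_max)


def _graclus_match(W: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One level of Graclus-style greedy matching.

    Nodes are visited in a seeded random order; each unmarked node pairs
    with the unmarked neighbor maximizing ``w_ij (1/d_i + 1/d_j)`` (ties
    broken by lowest node index), else stays a singleton. Returns the
    cluster id per node (cluster ids are 0..n_clusters-1 in visit order).
    """
    n = W.shape[0]
    d = W.sum(axis=1)
    marked = np.zeros(n, dtype=bool)
    cluster = -np.ones(n, dtype=int)
    cid = 0
    for i in rng.permutation(n):
        if marked[i]:
            continue
        marked[i] = True
        cluster[i] = cid
        nbrs = np.flatnonzero((W[i] > 0) & ~marked)
        if len(nbrs) and d[i] > 0:
            scores = W[i, nbrs] * (1.0 / d[i] + 1.0 / d[nbrs])
            j = nbrs[int(np.argmax(scores))]
            marked[j] = True
            cluster[j] = cid
        cid += 1
    return cluster


def _coarse_adjacency(W: np.ndarray, cluster: np.ndarray) -> np.ndarray:
    """Sum inter-cluster weights; intra-cluster weight is discarded."""
    m = cluster.max() + 1
    P = np.zeros((W.shape[0], m))
    P[np.arange(W.shape[0]), cluster] = 1.0
    Wc = P.T @ W @ P
    np.fill_diagonal(Wc, 0.0)
    return Wc


@dataclass
class CoarseningHierarchy:
    """A binary-tree coarsening of a graph, padded with fake nodes.

    ``graphs[l]`` is the padded, permuted graph at level ``l`` (level 0 is
    the finest); fake nodes have degree 0 and, at level 0, carry no real
    gene. ``perm0`` maps each level-0 slot to the original node index, or
    -1 for a fake slot. In padded order the parent of slot ``k`` at any
    level is slot ``k // 2`` of the next level, i.e. siblings are adjacent.
    ``cluster_maps[l]`` gives, per original-order real node of level ``l``,
    its cluster id at level ``l+1`` (before padding) — used for invariants
    and per-cluster pooling oracles.
    """

    graphs: list
    perm0: np.ndarray
    cluster_maps: list = field(default_factory=list)
    slot_maps: list = field(default_factory=list)
    n_real: int = 0

    @property
    def n_levels(self) -> int:
        return len(self.graphs) - 1

    @property
    def n_fake(self) -> int:
        return int((self.perm0 < 0).sum())

    def level_sizes(self) -> list:
        return [g.shape[0] for g in self.graphs]

    def scaled_laplacians(self, lambda_max=None) -> list:
        """Scaled Laplacians of each padded level (fake nodes isolated)."""
        out = []
        for A in self.graphs:
            if not A.any():
                out.append(ScaledLaplacian(-np.eye(A.shape[0]), 0.0))
                continue
            L = normalized_laplacian(PPIGraph(list(range(A.shape[0])), A))
            out.append(scale_laplacian(L, lambda_max))
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "level_sizes": self.level_sizes(),
                "perm0": self.perm0.tolist(),
                "n_real": self.n_real,
                "n_fake": self.n_fake,
                "cluster_maps": [c.tolist() for c in self.cluster_maps],
            }
        )


def coarsen(g: PPIGraph, n_levels: int = 2, seed: int = 0) -> CoarseningHierarchy:
    """Coarsen a graph ``n_levels`` times and build the pooling permutation.

    Each level applies Graclus-style greedy matching (randomized visit order
    under ``seed``); unmatched nodes become singletons. Fake disconnected
    nodes are then inserted so every parent has exactly two children, which
    makes ``|level l| = 2 |level l+1|`` and lets size-2 1-D max pooling act
    as graph pooling on the permuted signal.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if g.n_nodes == 0:
        raise ValueError("cannot coarsen an empty graph")
    rng = np.random.default_rng(seed)
    adjs = [g.adjacency]
    cluster_maps = []
    W = g.adjacency
    for _ in range(n_levels):
        cluster = _graclus_match(W, rng)
        cluster_maps.append(cluster)
        W = _coarse_adjacency(W, cluster)
        adjs.append(W)

    # Build per-level slot orderings from the coarsest level down: every
    # parent slot expands to its (<=2) real children plus fake children as
    # needed, so siblings are adjacent and each level doubles in size.
    orders = [list(range(adjs[-1].shape[0]))]
    for cluster in reversed(cluster_maps):
        parent_order = orders[-1]
        n_real_here = len(cluster)
        next_fake = n_real_here
        order = []
        for p in parent_order:
            children = list(np.flatnonzero(cluster == p)) if p < cluster.max() + 1 else []
            while len(children) < 2:
                children.append(next_fake)
                next_fake += 1
            order.extend(children)
        orders.append(order)
    orders.reverse()  # orders[l] = slot -> pre-padding node index at level l

    padded = []
    for A, order in zip(adjs, orders):
        size = len(order)
        n_real_here = A.shape[0]
        Ap = np.zeros((size, size))
        real_slots = [k for k, idx in enumerate(order) if idx < n_real_here]
        idxs = [order[k] for k in real_slots]
        Ap[np.ix_(real_slots, real_slots)] = A[np.ix_(idxs, idxs)]
        padded.append(Ap)

    slot_maps = [
        np.array([idx if idx < A.shape[0] else -1 for idx in order], dtype=int)
        for A, order in zip(adjs, orders)
    ]
    return CoarseningHierarchy(
        graphs=padded,
        perm0=slot_maps[0],
        cluster_maps=cluster_maps,
        slot_maps=slot_maps,
        n_real=g.n_nodes,
    )


def permute_signal(x: np.ndarray, h: CoarseningHierarchy) -> np.ndarray:
    """Reorder and pad a per-node signal for binary-tree pooling.

    ``x`` has one row per real level-0 node (extra trailing axes allowed);
    the output has one row per padded level-0 slot, with fake slots filled
    with 0 — neutral for max pooling because pooling is applied after a
    non-negative activation.
    """
    x = np.asarray(x)
    if x.shape[0] != h.n_real:
        raise ValueError(
            f"signal has {x.shape[0]} entries but the graph has {h.n_real} real nodes"
        )
    out_shape = (len(h.perm0),) + x.shape[1:]
    out = np.zeros(out_shape, dtype=float)
    real = h.perm0 >= 0
    out[real] = x[h.perm0[real]]
    return out
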