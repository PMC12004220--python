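"""Gene neighborhood graphs and Markov clustering (steps ii-iii).

Two graph constructions are offered on the selected genes:

* ``closest_neighborhood`` — an edge joins genes A and B when B belongs to
  the S nearest neighbors of A (S < K); the directed relations are
  symmetrized by union.
* ``reciprocal_neighborhood`` — an edge joins A and B only when each is
  among the other's K nearest neighbors (mutual-KNN); more edges are pruned,
  so a larger K is recommended.

The graph is then partitioned with the Markov Cluster algorithm (MCL): a
column-stochastic flow matrix is alternately expanded (matrix power,
extending random walks) and inflated (entrywise power + renormalization,
sharpening the walk) until it stabilizes; clusters are read off the
supports of attractor rows. Neighborhoods are computed among the selected
genes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .distance import DistanceMatrix, gene_distance_matrix
from .errors import ParameterError
from .matrix import ExpressionMatrix
from .moduleset import ModuleSet
from .selection import DknnResult

CLOSEST = "closest_neighborhood"
RECIPROCAL = "reciprocal_neighborhood"
_METHODS = (CLOSEST, RECIPROCAL)


@dataclass(frozen=True)
class GraphParams:
    """Neighborhood-graph construction parameters.

    ``s_closest`` (S) is only used by the closest_neighborhood method and
    must satisfy S < K.
    """

    method: str = CLOSEST
    s_closest: int = 5
    k_neighbors: int = 50

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ParameterError(f"method must be one of {_METHODS}")
        if self.k_neighbors < 1:
            raise ParameterError("k_neighbors must be >= 1")
        if self.method == CLOSEST:
            if self.s_closest < 1:
                raise ParameterError("s_closest must be >= 1")
            if self.s_closest >= self.k_neighbors:
                raise ParameterError("closest_neighborhood requires S < K")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "s_closest": self.s_closest,
            "k_neighbors": self.k_neighbors,
        }


@dataclass(frozen=True)
class MclParams:
    """Markov Cluster parameters.

    ``inflation`` (> 1) controls granularity: larger values give more,
    smaller clusters. ``expansion`` is the matrix-power exponent (2 is the
    standard random-walk extension).
    """

    inflation: float = 1.2
    expansion: int = 2
    pruning_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.inflation > 1.0:
            raise ParameterError("inflation must be > 1")
        if self.expansion < 2:
            raise ParameterError("expansion must be an integer >= 2")
        if self.pruning_threshold < 0:
            raise ParameterError("pruning_threshold must be non-negative")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")

    def to_dict(self) -> dict:
        return {
            "inflation": self.inflation,
            "expansion": self.expansion,
            "pruning_threshold": self.pruning_threshold,
            "max_iterations": self.max_iterations,
            "convergence_tol": self.convergence_tol,
        }


@dataclass
class GeneGraph:
    """Undirected, unweighted graph on gene nodes.

    Edges are stored as sorted (a, b) tuples with a < b; every edge has
    weight 1.
    """

    nodes: list[str]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for a, b in self.edges:
            if a == b:
                raise ParameterError(f"self-loop edge on {a!r}")
            if a > b:
                raise ParameterError("edges must be stored as sorted tuples")
            if a not in node_set or b not in node_set:
                raise ParameterError(f"edge ({a}, {b}) references unknown node")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> sp.csr_matrix:
        """0/1 adjacency in node order (no self-loops)."""
        index = {g: i for i, g in enumerate(self.nodes)}
        n = len(self.nodes)
        if not self.edges:
            return sp.csr_matrix((n, n))
        rows, cols = [], []
        for a, b in self.edges:
            i, j = index[a], index[b]
            rows += [i, j]
            cols += [j, i]
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def write_edges_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\n")
            for a, b in sorted(self.edges):
                fh.write(f"{a}\t{b}\n")


# --------------------------------------------------------------------------
# Graph builders
# --------------------------------------------------------------------------


def _neighbor_lists(d: DistanceMatrix, selected: Sequence[str], n_neighbors: int):
    """Indices of each selected gene's n nearest neighbors among selected.

    Ties are broken by gene order (stable argsort), making the construction
    deterministic.
    """
    sub = d.subset(list(selected))
    vals = sub.values.copy()
    np.fill_diagonal(vals, np.inf)
    order = np.argsort(vals, axis=1, kind="stable")
    return sub.gene_ids, order[:, :n_neighbors]


def _check_graph_pre(d: DistanceMatrix, selected: Sequence[str], k: int, name: str):
    known = set(d.gene_ids)
    missing = [g for g in selected if g not in known]
    if missing:
        raise ParameterError(f"selected genes absent from distance matrix: {missing[:5]}")
    if len(selected) <= k:
        raise ParameterError(
            f"{name} needs at least {k + 1} selected genes, got {len(selected)}"
        )


def build_closest_neighborhood_graph(
    d: DistanceMatrix, selected: Sequence[str], s_closest: int, k_neighbors: int
) -> GeneGraph:
    """Union-symmetrized S-nearest-neighbor graph on the selected genes."""
    if not 1 <= s_closest < k_neighbors:
        raise ParameterError("closest_neighborhood requires 1 <= S < K")
    _check_graph_pre(d, selected, s_closest, "closest_neighborhood (S)")
    genes, nn = _neighbor_lists(d, selected, s_closest)
    edges: set[tuple[str, str]] = set()
    for i, row in enumerate(nn):
        for j in row:
            a, b = genes[i], genes[int(j)]
            edges.add((a, b) if a < b else (b, a))
    return GeneGraph(list(genes), edges)


def build_reciprocal_graph(
    d: DistanceMatrix, selected: Sequence[str], k_neighbors: int
) -> GeneGraph:
    """Mutual-KNN graph: an edge requires membership in both neighborhoods."""
    if k_neighbors < 1:
        raise ParameterError("k_neighbors must be >= 1")
    _check_graph_pre(d, selected, k_neighbors, "reciprocal_neighborhood (K)")
    genes, nn = _neighbor_lists(d, selected, k_neighbors)
    neighbor_sets = [set(map(int, row)) for row in nn]
    edges: set[tuple[str, str]] = set()
    for i, row in enumerate(neighbor_sets):
        for j in row:
            # each unordered pair is examined once, from its smaller index
            if j > i and i in neighbor_sets[j]:
                a, b = genes[i], genes[j]
                edges.add((a, b) if a < b else (b, a))
    return GeneGraph(list(genes), edges)


# --------------------------------------------------------------------------
# Markov clustering
# --------------------------------------------------------------------------


def _colnorm(m: sp.csc_matrix) -> sp.csc_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    inv = sp.diags(1.0 / sums)
    return (m @ inv).tocsc()


def mcl_cluster(graph: GeneGraph, params: MclParams | None = None) -> ModuleSet:
    """Partition a gene graph with the Markov Cluster algorithm.

    Self-loops of weight 1 are added, columns normalized to sum 1, and the
    flow matrix iterated with expansion (matrix power), inflation
    (entrywise power + renormalization) and pruning of entries below
    ``pruning_threshold`` until the maximum entry change drops below
    ``convergence_tol``. Clusters are the supports of attractor rows
    (nodes with positive diagonal); overlapping attractor systems are
    merged and unattached nodes become singletons.

    The returned ModuleSet's provenance records iteration diagnostics,
    including the worst column-sum deviation after each normalization
    (``mcl_max_colsum_dev``) and a ``mcl_converged`` flag.
    """
    params = params or MclParams()
    if graph.n_nodes == 0:
        raise ParameterError("cannot cluster an empty graph")
    n = graph.n_nodes
    a = graph.adjacency().tolil()
    a.setdiag(1.0)  # standard MCL self-loops
    m = _colnorm(a.tocsc())
    colsum_dev: list[float] = []

    def record(mat: sp.csc_matrix) -> None:
        sums = np.asarray(mat.sum(axis=0)).ravel()
        colsum_dev.append(float(np.abs(sums - 1.0).max(initial=0.0)))

    record(m)
    converged = False
    n_iter = 0
    for n_iter in range(1, params.max_iterations + 1):
        prev = m
        # expansion: extend the random walk
        expanded = m
        for _ in range(params.expansion - 1):
            expanded = (expanded @ m).tocsc()
        m = expanded
        # inflation: sharpen the walk
        m = m.copy()
        m.data = np.power(m.data, params.inflation)
        m = _colnorm(m)
        record(m)
        # pruning: drop negligible flow, then renormalize
        if params.pruning_threshold > 0:
            m.data[m.data < params.pruning_threshold] = 0.0
            m.eliminate_zeros()
            m = _colnorm(m)
            record(m)
        diff = sp.csc_matrix(m - prev)
        change = float(np.abs(diff.data).max(initial=0.0))
        if change < params.convergence_tol:
            converged = True
            break

    clusters = _interpret_flow(m.tocsr(), graph.nodes)
    provenance = {
        "graph_nodes": n,
        "graph_edges": graph.n_edges,
        "mcl_params": params.to_dict(),
        "mcl_iterations": n_iter,
        "mcl_converged": converged,
        "mcl_max_colsum_dev": colsum_dev,
        "warnings": [] if converged else ["MCL did not converge; current flow interpreted"],
    }
    return ModuleSet.from_gene_lists(clusters, provenance)


def _interpret_flow(m: sp.csr_matrix, nodes: Sequence[str]) -> list[list[str]]:
    """Read clusters from a (near-)idempotent MCL flow matrix."""
    diag = m.diagonal()
    attractors = np.where(diag > 0)[0]
    clusters: list[set[int]] = []
    for i in attractors:
        support = set(m.indices[m.indptr[i]:m.indptr[i + 1]][
            m.data[m.indptr[i]:m.indptr[i + 1]] > 0
        ].tolist())
        support.add(int(i))
        merged = [c for c in clusters if c & support]
        for c in merged:
            support |= c
            clusters.remove(c)
        clusters.append(support)
    assigned = set().union(*clusters) if clusters else set()
    singleton_ids = [i for i in range(len(nodes)) if i not in assigned]
    out = [[nodes[i] for i in sorted(c)] for c in clusters]
    out.extend([[nodes[i]] for i in singleton_ids])
    return out


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------


def partition_genes(
    m: ExpressionMatrix,
    sel: DknnResult,
    graph_params: GraphParams | None = None,
    mcl_params: MclParams | None = None,
) -> ModuleSet:
    """Build the neighborhood graph on the selected genes and run MCL.

    Distances among the selected genes are computed with the metric used
    for selection; provenance records every parameter of the run.
    """
    graph_params = graph_params or GraphParams()
    mcl_params = mcl_params or MclParams()
    if not sel.selected_genes:
        raise ParameterError("no genes selected; nothing to partition")
    sub = m.subset_genes(sel.selected_genes)
    d = gene_distance_matrix(sub, sel.params.metric)
    if graph_params.method == CLOSEST:
        graph = build_closest_neighborhood_graph(
            d, sel.selected_genes, graph_params.s_closest, graph_params.k_neighbors
        )
    else:
        graph = build_reciprocal_graph(d, sel.selected_genes, graph_params.k_neighbors)
    ms = mcl_cluster(graph, mcl_params)
    prov = dict(ms.provenance)
    prov["selection_params"] = sel.params.to_dict()
    prov["graph_params"] = graph_params.to_dict()
    prov["dknn_threshold"] = sel.threshold
    prov["fdr_at_threshold"] = sel.fdr_at_threshold
    return ModuleSet(dict(ms.modules), prov)
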