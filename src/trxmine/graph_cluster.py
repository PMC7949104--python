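"""Weighted similarity graphs and Markov clustering (MCL) of protein families.

The subfamily structure of the mined superfamily is recovered by the Markov
cluster algorithm: a column-stochastic matrix built from pairwise bit scores
is alternately expanded (matrix power) and inflated (entrywise power followed
by column renormalisation) until an attractor structure emerges; clusters are
the components of that structure.  The implementation here is deliberately
self-contained and dense — the target problem sizes are thousands of nodes,
not millions — with an inflation default of 6, which favours fine-grained
subfamilies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json
import warnings

import networkx as nx
import numpy as np

from .errors import DataError


@dataclass
class MclParams:
    inflation: float = 6.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise DataError("inflation must be > 1")
        if self.expansion < 2:
            raise DataError("expansion must be >= 2")


@dataclass
class Clustering:
    """A partition of the graph's node set, plus the converged matrix."""

    clusters: list[frozenset[str]]
    params: MclParams
    converged: bool = True
    n_iterations: int = 0
    final_matrix: np.ndarray | None = None
    node_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cluster in self.clusters:
            if not cluster:
                raise AssertionError("empty cluster in partition")
            if seen & cluster:
                raise AssertionError("clusters overlap; not a partition")
            seen |= cluster

    @property
    def node_set(self) -> set[str]:
        out: set[str] = set()
        for c in self.clusters:
            out |= c
        return out

    def membership(self) -> dict[str, int]:
        """Map node -> cluster index, clusters ordered by decreasing size."""
        ordered = sorted(self.clusters, key=lambda c: (-len(c), min(c)))
        return {node: idx for idx, c in enumerate(ordered) for node in c}


def build_graph(similarities) -> nx.Graph:
    """Build an undirected weighted graph from (id1, id2, bit_score) triples.

    Duplicate pairs keep the maximum score; self-pairs are dropped; scores
    must be positive.
    """
    g = nx.Graph()
    for id1, id2, score in similarities:
        score = float(score)
        if score <= 0:
            raise DataError(f"similarity score must be > 0 ({id1!r}-{id2!r}: {score})")
        g.add_node(str(id1))
        g.add_node(str(id2))
        if id1 == id2:
            continue
        u, v = str(id1), str(id2)
        if g.has_edge(u, v):
            g[u][v]["weight"] = max(g[u][v]["weight"], score)
        else:
            g.add_edge(u, v, weight=score)
    return g


def read_similarity_table(path: str | Path):
    """Yield (id1, id2, score) from a 3-column tab-separated file (no header
    required; a header line starting with 'id1' is skipped)."""
    triples = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("id1"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"similarity line needs 3 columns: {line!r}")
            triples.append((parts[0], parts[1], float(parts[2])))
    return triples


def _stochastic(matrix: np.ndarray) -> np.ndarray:
    colsum = matrix.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return matrix / colsum


def mcl(graph: nx.Graph, params: MclParams | None = None) -> Clustering:
    """Run Markov clustering on a weighted similarity graph.

    Self-loops are added with weight equal to each node's maximum incident
    edge weight (1 for isolated nodes) before normalisation.  After
    convergence, rows with a nonzero diagonal are attractors; each cluster is
    an attractor together with the nodes attracted to it, with overlapping
    attractor systems merged so the result is a partition.  Nodes in
    different connected components can never be co-clustered.
    """
    if params is None:
        params = MclParams()
    if graph.number_of_nodes() == 0:
        raise DataError("cannot cluster an empty graph")
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    A = np.zeros((n, n))
    for u, v, w in graph.edges(data="weight"):
        A[index[u], index[v]] = w
        A[index[v], index[u]] = w
    loop = A.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(A, loop)

    M = _stochastic(A)
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        M_new = np.linalg.matrix_power(M, params.expansion)
        M_new = _stochastic(np.power(M_new, params.inflation))
        # prune tiny entries but never a column's maximum, then renormalise
        keep = M_new >= params.prune_threshold
        keep[M_new.argmax(axis=0), np.arange(n)] = True
        M_new = _stochastic(np.where(keep, M_new, 0.0))
        diff = np.abs(M_new - M).max()
        M = M_new
        if diff < params.convergence_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge in {params.max_iterations} iterations "
            f"(interpreting current matrix)",
            RuntimeWarning,
            stacklevel=2,
        )

    clusters = attractor_clusters(M, nodes)
    return Clustering(
        clusters=clusters,
        params=params,
        converged=converged,
        n_iterations=iterations,
        final_matrix=M,
        node_order=nodes,
    )


def attractor_clusters(matrix: np.ndarray, nodes: list[str]) -> list[frozenset[str]]:
    """Interpret a (converged) MCL matrix as a partition.

    Attractors are rows with a positive diagonal entry; node j belongs with
    attractor i when matrix[i, j] > 0.  Overlapping attractor systems are
    merged via connected components; any node attracted to nothing becomes a
    singleton.
    """
    n = len(nodes)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    attractors = np.flatnonzero(np.diagonal(matrix) > 0)
    for i in attractors:
        for j in np.flatnonzero(matrix[i] > 0):
            g.add_edge(int(i), int(j))
    return [
        frozenset(nodes[i] for i in comp) for comp in nx.connected_components(g)
    ]


def cluster_sizes(clustering: Clustering) -> list[int]:
    """Cluster sizes in descending order; their sum is the node count."""
    return sorted((len(c) for c in clustering.clusters), reverse=True)


def write_clustering(clustering: Clustering, table_path: str | Path,
                     summary_path: str | Path | None = None) -> None:
    member = clustering.membership()
    with open(table_path, "w") as fh:
        fh.write("seq_id\tcluster_index\n")
        for node in sorted(member, key=lambda x: (member[x], x)):
            fh.write(f"{node}\t{member[node]}\n")
    if summary_path is not None:
        summary = {
            "n_nodes": len(member),
            "n_clusters": len(clustering.clusters),
            "sizes": cluster_sizes(clustering),
            "converged": clustering.converged,
            "n_iterations": clustering.n_iterations,
            "inflation": clustering.params.inflation,
        }
        Path(summary_path).write_text(json.dumps(summary, indent=2))
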