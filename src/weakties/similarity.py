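"""Walk-polynomial topological similarity.

Pairwise similarity is the truncated walk sum

    S = M + beta * M^2 + beta^2 * M^3,

where M is either the 0/1 adjacency matrix (plain topological similarity)
or the bridgeness-derived weight matrix W with W_{uv} = exp(-B(u, v)) on
edges (weighted similarity).  (M^k)_{uv} sums the strengths of all walks of
length k from u to v, a walk's strength being the product of its edge
weights; beta < 1 down-weights longer walks.  The polynomial is truncated at
cubic order deliberately — vertices farther than three steps apart score 0.

Diagonal entries (closed-walk sums) are computed but never consulted
downstream: the virtual network has no self-loops and attachment closeness
sums only over core members distinct from the candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .bridgeness import EdgeScoreTable, score_all_edges

__all__ = [
    "SimilarityMatrix",
    "walk_similarity",
    "weight_from_bridgeness",
    "topological_similarity",
    "pairwise_similarity",
    "edge_similarity_table",
    "DEFAULT_BETA",
    "SPARSE_THRESHOLD",
]

DEFAULT_BETA = 0.618
# above this vertex count matrix powers are done sparsely
SPARSE_THRESHOLD = 2000


@dataclass
class SimilarityMatrix:
    """Symmetric nonnegative pairwise similarity over an ordered vertex index."""

    vertices: tuple
    matrix: object  # dense ndarray or scipy.sparse matrix
    beta: float
    source: str = "unweighted"  # or "weighted"
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.vertices = tuple(self.vertices)
        self._index = {v: i for i, v in enumerate(self.vertices)}
        n = len(self.vertices)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match vertex index")

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.matrix)

    def index_of(self, u) -> int:
        return self._index[u]

    def value(self, u, v) -> float:
        i, j = self._index[u], self._index[v]
        return float(self.matrix[i, j])

    def dense(self) -> np.ndarray:
        return self.matrix.toarray() if self.is_sparse else self.matrix

    def to_tsv(self, sink) -> None:
        """Dump the strictly-positive upper triangle as ``u v score`` TSV."""
        lines = [f"# beta={self.beta} source={self.source}", "u\tv\tscore"]
        mat = self.matrix.tocoo() if self.is_sparse else None
        if mat is not None:
            entries = [
                (self.vertices[i], self.vertices[j], v)
                for i, j, v in zip(mat.row, mat.col, mat.data)
                if i < j and v > 0
            ]
        else:
            ii, jj = np.nonzero(np.triu(self.matrix, k=1))
            entries = [
                (self.vertices[i], self.vertices[j], self.matrix[i, j]) for i, j in zip(ii, jj)
            ]
        for u, v, s in sorted(entries, key=lambda t: (str(t[0]), str(t[1]))):
            lines.append(f"{u}\t{v}\t{s:.10g}")
        if isinstance(sink, (str, Path)):
            with open(sink, "wt", encoding="utf-8") as handle:
                handle.write("\n".join(lines) + "\n")
        else:
            sink.write("\n".join(lines) + "\n")


def _check_symmetric(matrix) -> None:
    if sp.issparse(matrix):
        delta = abs(matrix - matrix.T)
        asym = delta.max() if delta.nnz else 0.0
    else:
        asym = float(np.abs(matrix - matrix.T).max()) if matrix.size else 0.0
    if asym > 1e-12:
        raise ValueError(f"input matrix is not symmetric (max asymmetry {asym})")


def walk_similarity(matrix, beta: float) -> object:
    """Truncated walk polynomial M + beta*M^2 + beta^2*M^3 of a symmetric M."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    _check_symmetric(matrix)
    m2 = matrix @ matrix
    m3 = m2 @ matrix
    return matrix + beta * m2 + beta * beta * m3


def weight_from_bridgeness(scores: EdgeScoreTable, sparse: bool = False):
    """Build the weighted adjacency W_{uv} = exp(-B(u, v)) from a bridgeness table.

    Returns ``(vertices, W)``: the ordered vertex index and a symmetric
    matrix with entries in (0, 1] on edges and 0 elsewhere.
    """
    if scores.variant not in ("reference", "weakties"):
        raise ValueError("weights require a bridgeness score table")
    vertices = tuple(scores.vertices)
    index = {v: i for i, v in enumerate(vertices)}
    n = len(vertices)
    if sparse:
        rows, cols, vals = [], [], []
        for (u, v), b in scores.items():
            i, j = index[u], index[v]
            w = math.exp(-b)
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        mat = sp.csr_array((vals, (rows, cols)), shape=(n, n))
    else:
        mat = np.zeros((n, n))
        for (u, v), b in scores.items():
            w = math.exp(-b)
            mat[index[u], index[v]] = w
            mat[index[v], index[u]] = w
    return vertices, mat


def topological_similarity(
    net: nx.Graph,
    beta: float = DEFAULT_BETA,
    sparse_threshold: int = SPARSE_THRESHOLD,
) -> SimilarityMatrix:
    """Walk similarity of the unweighted 0/1 adjacency matrix."""
    vertices = tuple(sorted(net.nodes(), key=str))
    if len(vertices) > sparse_threshold:
        adj = nx.to_scipy_sparse_array(net, nodelist=vertices, format="csr", dtype=float)
    else:
        adj = nx.to_numpy_array(net, nodelist=vertices)
    return SimilarityMatrix(
        vertices=vertices, matrix=walk_similarity(adj, beta), beta=beta, source="unweighted"
    )


def pairwise_similarity(
    net: nx.Graph,
    beta: float = DEFAULT_BETA,
    variant: str = "weakties",
    sparse_threshold: int = SPARSE_THRESHOLD,
) -> SimilarityMatrix:
    """Bridgeness-weighted walk similarity: score edges, weight, walk-sum."""
    scores = score_all_edges(net, variant=variant)
    vertices, weights = weight_from_bridgeness(scores, sparse=len(scores.vertices) > sparse_threshold)
    return SimilarityMatrix(
        vertices=vertices, matrix=walk_similarity(weights, beta), beta=beta, source="weighted"
    )


def edge_similarity_table(net: nx.Graph, beta: float = DEFAULT_BETA) -> EdgeScoreTable:
    """Plain topological similarity restricted to the edges of the network.

    This is the score table driving similarity-ordered percolation.
    """
    sim = topological_similarity(net, beta=beta)
    scores = {(u, v): sim.value(u, v) for u, v in net.edges()}
    return EdgeScoreTable(variant="similarity", scores=scores, vertices=sim.vertices)
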