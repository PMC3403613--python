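"""Edge bridgeness scores.

Two per-edge bridgeness variants are provided.  The reference form scores an
edge (u, v) as

    B(u, v) = sqrt(C_u * C_v) / C_{u,v},

where C_u is the size of the largest clique containing u and C_{u,v} the
size of the largest clique containing the edge.  Every edge inside a clique
scores exactly 1, so the reference form cannot distinguish small cliques
(whose edges are plausibly bridges) from large ones.

The weak-tie form fixes this by discounting with the open-neighborhood
Jaccard similarity J(u, v) and by measuring the clique context of each
endpoint with the other endpoint removed:

    B(u, v) = (1 - J(u, v)) * sqrt(C_{u\\v} * C_{v\\u}) / C_{u,v}.

On an isolated m-clique this equals 2(m-1)/m^2, strictly decreasing in m;
on a bridge between two cliques it is maximal.  Edges with high weak-tie
bridgeness are the weak ties that hold the network together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .cliques import DEFAULT_NEIGHBORHOOD_LIMIT, CliqueCache

__all__ = [
    "EdgeScoreTable",
    "jaccard",
    "bridgeness_reference",
    "bridgeness_weaktie",
    "score_all_edges",
    "VARIANTS",
]

VARIANTS = ("reference", "weakties", "similarity")


def _canonical(u, v) -> tuple:
    return (u, v) if str(u) <= str(v) else (v, u)


@dataclass
class EdgeScoreTable:
    """Per-edge scores for one network: a variant tag plus edge -> score.

    Contains exactly the edges of the source network; ``vertices`` records
    the full vertex set (isolated vertices included) so downstream matrix
    construction preserves it.
    """

    variant: str
    scores: dict = field(default_factory=dict)
    vertices: tuple = ()

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        self.scores = {_canonical(u, v): float(s) for (u, v), s in self.scores.items()}
        for edge, s in self.scores.items():
            if not math.isfinite(s) or s < 0:
                raise ValueError(f"score for {edge} must be finite and >= 0, got {s}")

    def __getitem__(self, edge):
        return self.scores[_canonical(*edge)]

    def __contains__(self, edge):
        return _canonical(*edge) in self.scores

    def __len__(self):
        return len(self.scores)

    def items(self):
        return self.scores.items()

    def edges(self):
        return self.scores.keys()

    def to_tsv(self, sink) -> None:
        lines = [f"# variant={self.variant}", "u\tv\tscore"]
        for (u, v) in sorted(self.scores):
            lines.append(f"{u}\t{v}\t{self.scores[(u, v)]:.10g}")
        if isinstance(sink, (str, Path)):
            with open(sink, "wt", encoding="utf-8") as handle:
                handle.write("\n".join(lines) + "\n")
        else:
            sink.write("\n".join(lines) + "\n")


def jaccard(net: nx.Graph, u, v, closed: bool = False) -> float:
    """Jaccard similarity of the neighborhoods of u and v (0 when both empty).

    Open neighborhoods by default (u not counted as its own neighbor); the
    closed variant is exposed only for sensitivity analysis.
    """
    if u not in net:
        raise KeyError(f"unknown vertex {u!r}")
    if v not in net:
        raise KeyError(f"unknown vertex {v!r}")
    nu, nv = set(net[u]), set(net[v])
    if closed:
        nu.add(u)
        nv.add(v)
    union = nu | nv
    if not union:
        return 0.0
    return len(nu & nv) / len(union)


def bridgeness_reference(net: nx.Graph, u, v, cache: CliqueCache | None = None) -> float:
    """Reference bridgeness sqrt(C_u * C_v) / C_{u,v} of edge (u, v)."""
    if not net.has_edge(u, v):
        raise ValueError(f"({u!r}, {v!r}) is not an edge")
    cache = cache or CliqueCache(net)
    return math.sqrt(cache.vertex(u) * cache.vertex(v)) / cache.edge(u, v)


def bridgeness_weaktie(net: nx.Graph, u, v, cache: CliqueCache | None = None) -> float:
    """Weak-tie bridgeness (1 - J) * sqrt(C_{u\\v} * C_{v\\u}) / C_{u,v}."""
    if not net.has_edge(u, v):
        raise ValueError(f"({u!r}, {v!r}) is not an edge")
    cache = cache or CliqueCache(net)
    dissim = 1.0 - jaccard(net, u, v)
    return dissim * math.sqrt(cache.excluding(u, v) * cache.excluding(v, u)) / cache.edge(u, v)


def score_all_edges(
    net: nx.Graph,
    variant: str = "weakties",
    limit: int = DEFAULT_NEIGHBORHOOD_LIMIT,
) -> EdgeScoreTable:
    """Score every edge of ``net`` with the chosen bridgeness variant."""
    if variant not in ("reference", "weakties"):
        raise ValueError(f"variant must be 'reference' or 'weakties', got {variant!r}")
    cache = CliqueCache(net, limit=limit)
    fn = bridgeness_reference if variant == "reference" else bridgeness_weaktie
    scores = {_canonical(u, v): fn(net, u, v, cache=cache) for u, v in net.edges()}
    return EdgeScoreTable(variant=variant, scores=scores, vertices=tuple(sorted(net.nodes(), key=str)))
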