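"""Exact maximum-clique queries localized to a vertex or edge, plus maximal
clique enumeration.

These are the primitives under both bridgeness formulas and core mining: the
size of the largest clique containing a vertex u (C_u), containing an edge
(u,v) (C_{u,v}), and containing u once v has been deleted (C_{u\\v}).
Searches are exact, restricted to the relevant closed neighborhood; a size
guard raises rather than silently approximating when a neighborhood is too
large for exact search.  PPI neighborhoods are small, so exactness is cheap.
"""

from __future__ import annotations

import networkx as nx

__all__ = [
    "NeighborhoodTooLarge",
    "max_clique_size_with_vertex",
    "max_clique_size_with_edge",
    "max_clique_size_excluding",
    "enumerate_maximal_cliques",
    "CliqueCache",
]

DEFAULT_NEIGHBORHOOD_LIMIT = 200


class NeighborhoodTooLarge(RuntimeError):
    """A closed neighborhood exceeds the exact-search guard."""


def _check_limit(net: nx.Graph, u, limit: int) -> None:
    if limit is not None and net.degree(u) + 1 > limit:
        raise NeighborhoodTooLarge(
            f"closed neighborhood of {u!r} has {net.degree(u) + 1} vertices, "
            f"above the exact-search limit {limit}"
        )


def max_clique_size_with_vertex(net: nx.Graph, u, limit: int = DEFAULT_NEIGHBORHOOD_LIMIT) -> int:
    """Size of the largest clique that contains vertex ``u`` (>= 1)."""
    if u not in net:
        raise KeyError(f"unknown vertex {u!r}")
    _check_limit(net, u, limit)
    return max(len(c) for c in nx.find_cliques(net, nodes=[u]))


def max_clique_size_with_edge(net: nx.Graph, u, v, limit: int = DEFAULT_NEIGHBORHOOD_LIMIT) -> int:
    """Size of the largest clique containing both endpoints of edge (u, v)."""
    if not net.has_edge(u, v):
        raise ValueError(f"({u!r}, {v!r}) is not an edge")
    _check_limit(net, u, limit)
    _check_limit(net, v, limit)
    return max(len(c) for c in nx.find_cliques(net, nodes=[u, v]))


def max_clique_size_excluding(net: nx.Graph, u, v, limit: int = DEFAULT_NEIGHBORHOOD_LIMIT) -> int:
    """Size of the largest clique containing ``u`` in the graph with ``v`` deleted.

    If deleting ``v`` isolates ``u`` entirely the answer is 1 (the trivial
    clique {u}).
    """
    if u == v:
        raise ValueError("u and v must differ")
    if u not in net:
        raise KeyError(f"unknown vertex {u!r}")
    if v not in net:
        raise KeyError(f"unknown vertex {v!r}")
    _check_limit(net, u, limit)
    if not net.has_edge(u, v):
        # v is irrelevant to any clique through u
        return max_clique_size_with_vertex(net, u, limit=limit)
    view = nx.restricted_view(net, [v], [])
    return max(len(c) for c in nx.find_cliques(view, nodes=[u]))


def enumerate_maximal_cliques(net: nx.Graph, min_size: int = 1) -> list:
    """All inclusion-maximal cliques of size >= ``min_size``.

    Returns a list of frozensets in canonical order (members sorted, then
    lexicographic list order), each clique reported once.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    keys = sorted(
        (tuple(sorted(str(x) for x in c)), frozenset(c))
        for c in nx.find_cliques(net)
        if len(c) >= min_size
    )
    return [fs for _, fs in keys]


class CliqueCache:
    """Memoizes the three clique-size queries for one fixed graph.

    Bridgeness scoring touches the same C_u / C_{u,v} / C_{u\\v} values many
    times; the cache is bound to a graph instance and must not outlive
    mutations of it.
    """

    def __init__(self, net: nx.Graph, limit: int = DEFAULT_NEIGHBORHOOD_LIMIT):
        self.net = net
        self.limit = limit
        self._vertex: dict = {}
        self._edge: dict = {}
        self._excluding: dict = {}

    def vertex(self, u) -> int:
        if u not in self._vertex:
            self._vertex[u] = max_clique_size_with_vertex(self.net, u, limit=self.limit)
        return self._vertex[u]

    def edge(self, u, v) -> int:
        key = frozenset((u, v))
        if key not in self._edge:
            self._edge[key] = max_clique_size_with_edge(self.net, u, v, limit=self.limit)
        return self._edge[key]

    def excluding(self, u, v) -> int:
        key = (u, v)
        if key not in self._excluding:
            self._excluding[key] = max_clique_size_excluding(self.net, u, v, limit=self.limit)
        return self._excluding[key]
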