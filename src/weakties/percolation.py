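"""Edge-percolation diagnostics for the weak-ties effect.

Edges are deleted in score order (ascending or descending) in fixed-size
batches; after each batch two observables are recorded:

* R_GC — the fraction of vertices in the giant (largest) connected
  component;
* the normalized susceptibility  S~ = sum_{s < s_max} s^2 / N,  the sum of
  squared component sizes over all components except one largest, divided
  by the vertex count.  S~ spikes when the network disintegrates into many
  mid-sized fragments and stays low otherwise.

If weak ties dominate global connectivity, removing edges from the least
similar (or most bridge-like) end shatters the network far earlier than
removing from the other end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .bridgeness import EdgeScoreTable, score_all_edges
from .similarity import DEFAULT_BETA, edge_similarity_table

__all__ = [
    "PercolationTrajectory",
    "giant_component_fraction",
    "susceptibility",
    "percolation_experiment",
    "bridgeness_similarity_profile",
]


@dataclass
class PercolationTrajectory:
    """Ordered (fraction_removed, giant_fraction, susceptibility) records."""

    table: pd.DataFrame
    order: str
    variant: str

    @property
    def fraction_removed(self) -> np.ndarray:
        return self.table["fraction_removed"].to_numpy()

    @property
    def giant_fraction(self) -> np.ndarray:
        return self.table["giant_fraction"].to_numpy()

    @property
    def susceptibility(self) -> np.ndarray:
        return self.table["susceptibility"].to_numpy()

    def first_fraction_below(self, threshold: float) -> float:
        """Smallest removed fraction at which R_GC < threshold (inf if never)."""
        hit = self.table[self.table["giant_fraction"] < threshold]
        return float(hit["fraction_removed"].iloc[0]) if len(hit) else math.inf

    def to_tsv(self, sink) -> None:
        header = f"# order={self.order} variant={self.variant}\n"
        text = self.table.to_csv(sep="\t", index=False)
        if isinstance(sink, (str, Path)):
            with open(sink, "wt", encoding="utf-8") as handle:
                handle.write(header + text)
        else:
            sink.write(header + text)


def _component_sizes(net: nx.Graph) -> list:
    return [len(c) for c in nx.connected_components(net)]


def giant_component_fraction(net: nx.Graph) -> float:
    """|largest connected component| / |V|."""
    if net.number_of_nodes() == 0:
        raise ValueError("giant component of an empty graph is undefined")
    return max(_component_sizes(net)) / net.number_of_nodes()


def susceptibility(net: nx.Graph) -> float:
    """Normalized susceptibility: sum of s^2 over non-giant components / N.

    Exactly one largest component is excluded when several tie for the
    maximum (the standard convention, which keeps the statistic meaningful
    at the transition).  Singletons count as size-1 components.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("susceptibility of an empty graph is undefined")
    sizes = sorted(_component_sizes(net))
    sizes.pop()  # one largest component excluded
    return sum(s * s for s in sizes) / net.number_of_nodes()


def percolation_experiment(
    net: nx.Graph,
    scores: EdgeScoreTable,
    order: str = "ascending",
    step_fraction: float = 0.01,
    tie_break: str = "lexicographic",
    seed: int = 0,
) -> PercolationTrajectory:
    """Remove edges in score order in batches, recording R_GC and S~.

    Scores are taken as computed on the intact graph and never refreshed
    during removal.  Ties are broken by lexicographic edge identity by
    default, keeping the trajectory deterministic; ``tie_break="random"``
    shuffles equal-score edges with the given seed for sensitivity checks.
    """
    if order not in ("ascending", "descending"):
        raise ValueError("order must be 'ascending' or 'descending'")
    if not (0 < step_fraction <= 1):
        raise ValueError("step_fraction must be in (0, 1]")
    if tie_break not in ("lexicographic", "random"):
        raise ValueError("tie_break must be 'lexicographic' or 'random'")
    edge_set = {tuple(sorted((str(u), str(v)))) for u, v in net.edges()}
    table_set = {tuple(sorted((str(u), str(v)))) for u, v in scores.edges()}
    if edge_set != table_set:
        raise ValueError("score table does not cover exactly the network's edges")

    reverse = order == "descending"
    items = list(scores.items())
    if tie_break == "random":
        rng = np.random.default_rng(seed)
        tags = rng.permutation(len(items))
        ranked = sorted(
            zip(items, tags),
            key=lambda pair: (-pair[0][1] if reverse else pair[0][1], pair[1]),
        )
        ordered_edges = [edge for (edge, _), _ in ranked]
    else:
        ranked = sorted(
            items,
            key=lambda kv: (-kv[1] if reverse else kv[1], tuple(str(x) for x in kv[0])),
        )
        ordered_edges = [edge for edge, _ in ranked]

    total = len(ordered_edges)
    working = net.copy()
    records = [(0.0, giant_component_fraction(working), susceptibility(working))]
    if total:
        batch = max(1, math.ceil(step_fraction * total))
        removed = 0
        while removed < total:
            chunk = ordered_edges[removed : removed + batch]
            working.remove_edges_from(chunk)
            removed += len(chunk)
            records.append(
                (removed / total, giant_component_fraction(working), susceptibility(working))
            )
    table = pd.DataFrame(records, columns=["fraction_removed", "giant_fraction", "susceptibility"])
    return PercolationTrajectory(table=table, order=order, variant=scores.variant)


def bridgeness_similarity_profile(
    net: nx.Graph, bins: int = 10, beta: float = DEFAULT_BETA
) -> list:
    """Mean weak-tie bridgeness of edges grouped into similarity quantile bins.

    Returns a list of ``(similarity bin center, mean bridgeness)`` pairs for
    the occupied bins, ordered by similarity.  Empty graphs give an empty
    profile.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if net.number_of_edges() == 0:
        return []
    sims = edge_similarity_table(net, beta=beta)
    brid = score_all_edges(net, variant="weakties")
    edges = sorted(sims.edges())
    s = np.array([sims[e] for e in edges])
    b = np.array([brid[e] for e in edges])
    quantiles = np.quantile(s, np.linspace(0, 1, bins + 1))
    quantiles = np.unique(quantiles)
    if len(quantiles) == 1:  # all edges share one similarity value
        return [(float(quantiles[0]), float(b.mean()))]
    which = np.clip(np.searchsorted(quantiles, s, side="right") - 1, 0, len(quantiles) - 2)
    profile = []
    for k in range(len(quantiles) - 1):
        mask = which == k
        if mask.any():
            center = 0.5 * (quantiles[k] + quantiles[k + 1])
            profile.append((float(center), float(b[mask].mean())))
    return profile
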