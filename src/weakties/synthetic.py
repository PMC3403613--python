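"""Synthetic core-attachment networks and robustness perturbations.

``planted_network`` emulates the core-attachment anatomy of protein
complexes: each planted complex is a dense core clique plus peripheral
attachment vertices linked to a fraction of the core; sparse bridge edges
connect cores of different complexes; independent background noise edges
blur the picture.  The generator returns the network together with the
ground-truth catalog, so every stage of the pipeline is testable without
external downloads.

``test_graph_from_catalog`` builds the union-of-cliques *test graph* from a
complex catalog (every within-complex pair connected), and ``alter_graph``
produces the perturbed graphs AG_add,del by deleting then adding random
edges; both percentages are taken relative to the intact test graph's edge
count, so an added edge may recreate a previously deleted one.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .evaluation import geometric_accuracy, separation
from .ppi_io import ComplexCatalog, ComplexRecord

__all__ = [
    "PlantedModel",
    "AlteredGraphSpec",
    "planted_network",
    "test_graph_from_catalog",
    "alter_graph",
    "robustness_experiment",
]


@dataclass
class PlantedModel:
    """Parameters of the planted core-attachment generator.

    Defaults describe a mid-sized benchmark: 20 complexes with cores of 4-8
    proteins, two attachments per complex each touching half the core, no
    bridges and no background noise (noise and bridges are switched on
    explicitly by experiments that study them).
    """

    complex_count: int = 20
    core_size_range: tuple = (4, 8)  # inclusive
    attachments_per_complex: int = 2
    attachment_link_fraction: float = 0.5
    background_noise_prob: float = 0.0
    bridge_edge_count: int = 0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.core_size_range
        if self.complex_count < 1:
            raise ValueError("complex_count must be >= 1")
        if lo < 2 or hi < lo:
            raise ValueError("core sizes must be >= 2 with a nonempty range")
        if self.attachments_per_complex < 0 or self.bridge_edge_count < 0:
            raise ValueError("counts must be >= 0")
        if not (0 < self.attachment_link_fraction <= 1):
            raise ValueError("attachment_link_fraction must be in (0, 1]")
        if not (0 <= self.background_noise_prob < 1):
            raise ValueError("background_noise_prob must be in [0, 1)")
        if self.bridge_edge_count and self.complex_count < 2:
            raise ValueError("bridges need at least two complexes")


def planted_network(model: PlantedModel) -> tuple:
    """Generate (network, ground-truth catalog); reproducible from the seed."""
    model.validate()
    rng = np.random.default_rng(model.seed)
    lo, hi = model.core_size_range
    net = nx.Graph()
    records = []
    cores = []
    for i in range(model.complex_count):
        size = int(rng.integers(lo, hi + 1))
        core = [f"c{i:03d}v{j}" for j in range(size)]
        cores.append(core)
        net.add_edges_from(itertools.combinations(core, 2))
        attachments = []
        n_links = math.ceil(model.attachment_link_fraction * size)
        for j in range(model.attachments_per_complex):
            a = f"c{i:03d}a{j}"
            attachments.append(a)
            targets = rng.choice(size, size=n_links, replace=False)
            net.add_edges_from((a, core[t]) for t in targets)
        records.append(
            ComplexRecord(
                members=frozenset(core) | frozenset(attachments),
                name=f"complex_{i}",
                core=frozenset(core),
            )
        )
    for _ in range(model.bridge_edge_count):
        for _attempt in range(200):
            a, b = rng.choice(model.complex_count, size=2, replace=False)
            u = cores[a][int(rng.integers(len(cores[a])))]
            v = cores[b][int(rng.integers(len(cores[b])))]
            if not net.has_edge(u, v):
                net.add_edge(u, v)
                break
        else:
            raise RuntimeError("could not place a bridge edge without duplication")
    if model.background_noise_prob > 0:
        vertices = sorted(net.nodes())
        for u, v in itertools.combinations(vertices, 2):
            if not net.has_edge(u, v) and rng.random() < model.background_noise_prob:
                net.add_edge(u, v)
    return net, ComplexCatalog(records)


def test_graph_from_catalog(catalog: ComplexCatalog) -> nx.Graph:
    """Union-of-cliques graph: every within-complex pair becomes an edge."""
    if len(catalog) == 0:
        raise ValueError("catalog must be nonempty")
    net = nx.Graph()
    for rec in catalog:
        members = sorted(rec.members)
        net.add_nodes_from(members)
        net.add_edges_from(itertools.combinations(members, 2))
    return net


@dataclass
class AlteredGraphSpec:
    """Perturbation AG_add,del: percentages relative to the intact edge count."""

    add_percent: float = 0.0
    del_percent: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.add_percent < 0:
            raise ValueError("add_percent must be >= 0")
        if not (0 <= self.del_percent <= 100):
            raise ValueError("del_percent must be in [0, 100]")


def alter_graph(net: nx.Graph, spec: AlteredGraphSpec) -> nx.Graph:
    """Delete then add uniformly random edges; vertex set preserved.

    Deletion removes floor(del% * |E|) uniformly chosen edges; addition then
    inserts floor(add% * |E_original|) uniformly chosen non-edges of the
    current graph, so a deleted edge may be recreated.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out = net.copy()
    edges = sorted(tuple(sorted(e)) for e in out.edges())
    n_original = len(edges)
    n_del = math.floor(spec.del_percent / 100 * n_original)
    if n_del:
        idx = rng.choice(n_original, size=n_del, replace=False)
        out.remove_edges_from(edges[i] for i in idx)
    n_add = math.floor(spec.add_percent / 100 * n_original)
    if n_add:
        vertices = sorted(out.nodes())
        non_edges = [
            (u, v) for u, v in itertools.combinations(vertices, 2) if not out.has_edge(u, v)
        ]
        if n_add > len(non_edges):
            raise ValueError(
                f"requested {n_add} additions but only {len(non_edges)} non-edges exist"
            )
        idx = rng.choice(len(non_edges), size=n_add, replace=False)
        out.add_edges_from(non_edges[i] for i in idx)
    return out


def robustness_experiment(
    catalog: ComplexCatalog,
    add_grid=(0,),
    del_grid=(0,),
    replicates: int = 1,
    seed: int = 0,
    detector_params: dict | None = None,
) -> pd.DataFrame:
    """Detection quality on altered test graphs over an add/del percentage grid.

    For every (add, del, replicate) cell the test graph is perturbed, the
    detector run with ``detector_params``, and the predictions scored with
    geometric accuracy and separation against the catalog.
    """
    from .detection import detect_complexes  # local import avoids a cycle

    params = dict(detector_params or {})
    base = test_graph_from_catalog(catalog)
    rows = []
    counter = 0
    for add in add_grid:
        for dele in del_grid:
            for rep in range(replicates):
                sub_seed = (int(seed) * 1_000_003 + counter) % (2**31 - 1)
                counter += 1
                altered = alter_graph(
                    base, AlteredGraphSpec(add_percent=add, del_percent=dele, seed=sub_seed)
                )
                predicted = detect_complexes(altered, **params)
                sn, ppv, acc = geometric_accuracy(catalog, predicted)
                sep_co, sep_cl, sep = separation(catalog, predicted)
                rows.append(
                    {
                        "add_percent": float(add),
                        "del_percent": float(dele),
                        "replicate": rep,
                        "n_predicted": len(predicted),
                        "sn": sn,
                        "ppv": ppv,
                        "acc": acc,
                        "sep_co": sep_co,
                        "sep_cl": sep_cl,
                        "sep": sep,
                    }
                )
    return pd.DataFrame(rows)
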