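"""Evaluation metrics for predicted complex sets.

Matching-based scores (F-measure, coverage rate) compare a predicted set PS
against a benchmark set BS through the neighborhood affinity

    NA(p, b) = |p & b|^2 / (|p| * |b|),

with two sets declared a match when NA >= t (default t = 0.2, the standard
choice in this evaluation lineage).  Clustering-wise scores (Sn, PPV, ACC,
Sep) work on the |BS| x |PS| overlap-count matrix T.  Functional enrichment
of a complex against an annotation group uses the hypergeometric upper tail
P(X >= k); no multiple-testing correction is applied and each complex is
assigned its smallest P-value over all groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .ppi_io import AnnotationGroups, ComplexCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "neighborhood_affinity",
    "overlap_matrix",
    "match_counts",
    "f_measure",
    "coverage_rate",
    "hypergeometric_pvalue",
    "geometric_accuracy",
    "separation",
    "evaluate",
    "enrichment",
    "complex_stats",
]

DEFAULT_NA_THRESHOLD = 0.2
DEFAULT_PVALUE_CUTOFF = 1e-2


def _member_sets(catalog) -> list:
    if isinstance(catalog, ComplexCatalog):
        return catalog.member_sets()
    return [frozenset(c) for c in catalog]


def neighborhood_affinity(p, b) -> float:
    """NA(p, b) = |p & b|^2 / (|p| * |b|), in [0, 1]."""
    p, b = frozenset(p), frozenset(b)
    if not p or not b:
        raise ValueError("neighborhood affinity of an empty set is undefined")
    inter = len(p & b)
    return inter * inter / (len(p) * len(b))


def overlap_matrix(bench, predicted) -> np.ndarray:
    """|BS| x |PS| matrix of shared-member counts T_ij."""
    bs = _member_sets(bench)
    ps = _member_sets(predicted)
    return np.array([[len(b & p) for p in ps] for b in bs], dtype=int).reshape(len(bs), len(ps))


def match_counts(predicted, bench, t: float = DEFAULT_NA_THRESHOLD) -> tuple:
    """(N_cp, N_cb): predictions matching >= 1 benchmark and vice versa."""
    if not (0 < t <= 1):
        raise ValueError("match threshold t must be in (0, 1]")
    ps = _member_sets(predicted)
    bs = _member_sets(bench)
    n_cp = sum(1 for p in ps if any(neighborhood_affinity(p, b) >= t for b in bs))
    n_cb = sum(1 for b in bs if any(neighborhood_affinity(p, b) >= t for p in ps))
    return n_cp, n_cb


def f_measure(predicted, bench, t: float = DEFAULT_NA_THRESHOLD) -> tuple:
    """(precision, recall, F): precision = N_cp/|PS|, recall = N_cb/|BS|."""
    ps = _member_sets(predicted)
    bs = _member_sets(bench)
    if not ps or not bs:
        logger.warning("empty predicted or benchmark set: F-measure defined as 0")
        return 0.0, 0.0, 0.0
    n_cp, n_cb = match_counts(ps, bs, t=t)
    precision = n_cp / len(ps)
    recall = n_cb / len(bs)
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f


def coverage_rate(bench, predicted) -> float:
    """sum_i max_j T_ij / sum_i N_i: benchmark membership recovered by best matches."""
    bs = _member_sets(bench)
    if not bs:
        raise ValueError("benchmark set must be nonempty")
    ps = _member_sets(predicted)
    if not ps:
        return 0.0
    t = overlap_matrix(bs, ps)
    return float(t.max(axis=1).sum() / sum(len(b) for b in bs))


def hypergeometric_pvalue(universe_size: int, group_size: int, complex_size: int, k: int) -> float:
    """Upper-tail P(X >= k) of the hypergeometric overlap distribution.

    ``universe_size`` is the PPI network size |V|, ``group_size`` the
    functional group size, ``complex_size`` the complex size and ``k`` the
    observed overlap.  Computed through scipy's survival function, which is
    log-stable; k = 0 gives exactly 1.
    """
    if not (0 <= k <= min(group_size, complex_size)):
        raise ValueError("overlap k must satisfy 0 <= k <= min(group, complex)")
    if group_size > universe_size or complex_size > universe_size:
        raise ValueError("group and complex sizes cannot exceed the universe")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe_size, group_size, complex_size))


def geometric_accuracy(bench, clusters) -> tuple:
    """(Sn, PPV, ACC) of clusters against annotated benchmark complexes.

    Sn = sum_i max_j T_ij / sum_i N_i;  PPV = sum_j max_i T_ij / sum_ij T_ij
    (columns with zero sum contribute nothing);  ACC = sqrt(Sn * PPV).
    """
    bs = _member_sets(bench)
    ps = _member_sets(clusters)
    if not bs or not ps:
        return 0.0, 0.0, 0.0
    t = overlap_matrix(bs, ps)
    n_total = sum(len(b) for b in bs)
    sn = float(t.max(axis=1).sum() / n_total)
    col_sums = t.sum(axis=0)
    denom = col_sums.sum()
    ppv = float(t.max(axis=0).sum() / denom) if denom > 0 else 0.0
    return sn, ppv, math.sqrt(sn * ppv)


def separation(bench, clusters) -> tuple:
    """(Sep_co, Sep_cl, Sep): row/column-normalized overlap products.

    Sep_ij = (T_ij / row_i sum) * (T_ij / column_j sum), with zero-sum rows
    or columns contributing 0;  Sep_co averages over the n benchmark
    complexes, Sep_cl over the m clusters, Sep = sqrt(Sep_co * Sep_cl).
    """
    bs = _member_sets(bench)
    ps = _member_sets(clusters)
    if not bs or not ps:
        return 0.0, 0.0, 0.0
    t = overlap_matrix(bs, ps).astype(float)
    row_sums = t.sum(axis=1, keepdims=True)
    col_sums = t.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        fcol = np.where(row_sums > 0, t / np.where(row_sums > 0, row_sums, 1), 0.0)
        ppv_ij = np.where(col_sums > 0, t / np.where(col_sums > 0, col_sums, 1), 0.0)
    sep_ij = fcol * ppv_ij
    total = float(sep_ij.sum())
    sep_co = total / len(bs)
    sep_cl = total / len(ps)
    return sep_co, sep_cl, math.sqrt(sep_co * sep_cl)


@dataclass
class EvaluationReport:
    """All matching and clustering-wise scores for one PS-vs-BS comparison."""

    n_predicted: int
    n_benchmark: int
    n_cp: int
    n_cb: int
    precision: float
    recall: float
    f_measure: float
    coverage_rate: float
    sn: float
    ppv: float
    acc: float
    sep_co: float
    sep_cl: float
    sep: float
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def evaluate(predicted, bench, t: float = DEFAULT_NA_THRESHOLD) -> EvaluationReport:
    """Full scorecard of a predicted catalog against a benchmark catalog."""
    ps = _member_sets(predicted)
    bs = _member_sets(bench)
    n_cp, n_cb = match_counts(ps, bs, t=t) if ps and bs else (0, 0)
    precision, recall, f = f_measure(ps, bs, t=t) if ps and bs else (0.0, 0.0, 0.0)
    cr = coverage_rate(bs, ps) if bs else 0.0
    sn, ppv, acc = geometric_accuracy(bs, ps)
    sep_co, sep_cl, sep = separation(bs, ps)
    return EvaluationReport(
        n_predicted=len(ps),
        n_benchmark=len(bs),
        n_cp=n_cp,
        n_cb=n_cb,
        precision=precision,
        recall=recall,
        f_measure=f,
        coverage_rate=cr,
        sn=sn,
        ppv=ppv,
        acc=acc,
        sep_co=sep_co,
        sep_cl=sep_cl,
        sep=sep,
        threshold=t,
    )


def enrichment(
    catalog,
    groups: AnnotationGroups,
    universe_size: int,
    cutoff: float = DEFAULT_PVALUE_CUTOFF,
) -> pd.DataFrame:
    """Best-group hypergeometric enrichment per complex.

    Each complex gets its smallest P-value over all annotation groups (no
    multiple-testing correction) and a ``significant`` flag at ``cutoff``.
    """
    rows = []
    sets = _member_sets(catalog)
    names = [
        c.name if getattr(c, "name", None) else f"complex_{i + 1}"
        for i, c in enumerate(catalog)
    ]
    for name, members in zip(names, sets):
        best = (None, 0, 1.0)
        for gname, gmembers in sorted(groups.items()):
            k = len(members & gmembers)
            p = hypergeometric_pvalue(universe_size, len(gmembers), len(members), k)
            if p < best[2]:
                best = (gname, k, p)
        rows.append(
            {
                "complex": name,
                "size": len(members),
                "best_group": best[0],
                "overlap": best[1],
                "p_value": best[2],
                "significant": best[2] < cutoff,
            }
        )
    return pd.DataFrame(rows)


def complex_stats(catalog, net: nx.Graph) -> pd.DataFrame:
    """Per-complex size and induced density on the original network.

    density = 2 |E(members)| / (|members| (|members| - 1)); singletons are
    reported with density 0 and a flag.
    """
    rows = []
    for i, rec in enumerate(catalog):
        members = rec.members if hasattr(rec, "members") else frozenset(rec)
        missing = [m for m in members if m not in net]
        if missing:
            raise KeyError(f"complex members not in network: {sorted(missing)[:5]}")
        n = len(members)
        name = getattr(rec, "name", None) or f"complex_{i + 1}"
        if n < 2:
            rows.append({"complex": name, "size": n, "density": 0.0, "singleton": True})
            continue
        e = net.subgraph(members).number_of_edges()
        rows.append(
            {"complex": name, "size": n, "density": 2 * e / (n * (n - 1)), "singleton": False}
        )
    return pd.DataFrame(rows)
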