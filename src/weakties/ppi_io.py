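"""Readers and writers for PPI edge lists, complex catalogs and GMT annotation groups.

All formats are plain text.  Lines starting with ``#`` are comments; a token
starting with ``#`` inside a line terminates that line's payload, so trailing
comments such as ``... #core-size=3`` are tolerated everywhere.  Protein
identifiers are case-sensitive opaque strings; no ORF/gene-name mapping is
attempted.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ComplexRecord",
    "ComplexCatalog",
    "AnnotationGroups",
    "read_edge_list",
    "write_edge_list",
    "read_complex_catalog",
    "write_complex_catalog",
    "read_annotation_groups",
]


class ParseError(ValueError):
    """Raised when a text input cannot be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def _open_lines(source) -> Iterator[str]:
    """Yield lines from a path, a text stream, or an iterable of strings."""
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as handle:
            yield from handle
    else:
        yield from source


def _payload_tokens(tokens: list[str]) -> list[str]:
    """Truncate a token list at the first token starting with '#'."""
    for i, tok in enumerate(tokens):
        if tok.startswith("#"):
            return tokens[:i]
    return tokens


def read_edge_list(source, allow_extra_columns: bool = False) -> nx.Graph:
    """Read a two-column interaction edge list into a simple undirected graph.

    Self-loops and duplicate edges are silently dropped (their counts are
    logged): real interaction dumps routinely contain both.  Columns beyond
    the first two raise unless ``allow_extra_columns`` is set.
    """
    net = nx.Graph()
    n_loops = 0
    n_dups = 0
    for lineno, raw in enumerate(_open_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = _payload_tokens(line.split())
        if len(tokens) < 2:
            raise ParseError(f"expected at least 2 columns, got {len(tokens)}", lineno)
        if len(tokens) > 2 and not allow_extra_columns:
            raise ParseError(
                f"unexpected extra columns ({len(tokens)} tokens); "
                "pass allow_extra_columns=True to ignore them",
                lineno,
            )
        u, v = tokens[0], tokens[1]
        if u == v:
            n_loops += 1
            net.add_node(u)
            continue
        if net.has_edge(u, v):
            n_dups += 1
            continue
        net.add_edge(u, v)
    if n_loops or n_dups:
        logger.info("dropped %d self-loops and %d duplicate edges", n_loops, n_dups)
    return net


def write_edge_list(net: nx.Graph, sink) -> None:
    """Write one edge per line, endpoints in lexicographic order, lines sorted."""
    lines = sorted(tuple(sorted((str(u), str(v)))) for u, v in net.edges())
    _write_lines(sink, ("\t".join(pair) for pair in lines))


def _write_lines(sink, lines: Iterable[str]) -> None:
    if isinstance(sink, (str, Path)):
        with open(sink, "wt", encoding="utf-8") as handle:
            for line in lines:
                handle.write(line + "\n")
    else:
        for line in lines:
            sink.write(line + "\n")


@dataclass(frozen=True)
class ComplexRecord:
    """One protein complex: a member set, an optional name, an optional core.

    ``core`` is populated by the detection pipeline (core-attachment output);
    catalogs read from disk leave it ``None``.
    """

    members: frozenset
    name: str | None = None
    core: frozenset | None = None

    def __post_init__(self):
        if not self.members:
            raise ValueError("a complex must have at least one member")
        if self.core is not None and not self.core <= self.members:
            raise ValueError("core must be a subset of members")

    @property
    def attachments(self) -> frozenset:
        return self.members - self.core if self.core is not None else frozenset()

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ComplexCatalog:
    """Ordered collection of complexes (predictions, benchmarks, or truth)."""

    complexes: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.complexes)

    def __len__(self):
        return len(self.complexes)

    def __getitem__(self, i):
        return self.complexes[i]

    def member_sets(self) -> list:
        return [c.members for c in self.complexes]

    def all_members(self) -> frozenset:
        out = set()
        for c in self.complexes:
            out |= c.members
        return frozenset(out)


def read_complex_catalog(source, named: bool = False) -> ComplexCatalog:
    """Read a one-complex-per-line catalog (whitespace-separated members).

    With ``named``, the first tab-delimited field is the complex name and the
    remainder holds the members.  Duplicate members within a line are
    collapsed with a warning; an empty member set is a parse error.
    """
    records = []
    for lineno, raw in enumerate(_open_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        name = None
        if named:
            fields = line.split("\t", 1)
            if len(fields) < 2:
                raise ParseError("named catalog line needs a tab after the name", lineno)
            name = fields[0].strip()
            member_part = fields[1]
        else:
            member_part = line
        tokens = _payload_tokens(member_part.split())
        if not tokens:
            raise ParseError("complex with empty member set", lineno)
        members = frozenset(tokens)
        if len(members) < len(tokens):
            logger.warning("line %d: %d duplicate members collapsed", lineno, len(tokens) - len(members))
        records.append(ComplexRecord(members=members, name=name))
    return ComplexCatalog(records)


def write_complex_catalog(catalog: ComplexCatalog, sink, named: bool | None = None) -> None:
    """Write a catalog, one complex per line, members sorted.

    For records with a core, core members are listed first (each group
    sorted) and a trailing ``#core-size`` comment is appended.  ``named``
    defaults to writing names whenever every record has one.
    """
    if named is None:
        named = all(c.name is not None for c in catalog)
    lines = []
    for rec in catalog:
        if rec.core is not None:
            members = sorted(rec.core) + sorted(rec.attachments)
            tail = f"\t#core-size={len(rec.core)}"
        else:
            members = sorted(rec.members)
            tail = ""
        prefix = f"{rec.name}\t" if named else ""
        lines.append(prefix + " ".join(members) + tail)
    _write_lines(sink, lines)


@dataclass
class AnnotationGroups:
    """Functional annotation groups: mapping group name -> member set."""

    groups: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.groups)

    def __len__(self):
        return len(self.groups)

    def __getitem__(self, name):
        return self.groups[name]

    def items(self):
        return self.groups.items()


def read_annotation_groups(source) -> AnnotationGroups:
    """Read GMT-format groups: name TAB description TAB member TAB member ..."""
    groups: dict = {}
    descriptions: dict = {}
    for lineno, raw in enumerate(_open_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"GMT line needs >= 3 tab-separated fields, got {len(fields)}", lineno)
        name, desc = fields[0], fields[1]
        members = frozenset(m for m in fields[2:] if m)
        if not members:
            raise ParseError("GMT group with no members", lineno)
        if name in groups:
            logger.warning("line %d: duplicate group %r, last definition wins", lineno, name)
        groups[name] = members
        descriptions[name] = desc
    return AnnotationGroups(groups=groups, descriptions=descriptions)
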