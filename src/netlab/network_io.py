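"""Ingestion, filtering, and merging of curated protein-protein interaction tables.

Interaction records carry a STRING-style combined confidence score in [0, 1]
and a free-text evidence tag.  Networks are undirected simple graphs
(``networkx.Graph``) whose nodes are uppercase gene symbols annotated with a
small-GTPase subfamily label (``RHO``, ``RAS``, ``RAB``, ``ARF``, ``RAN``,
``RGK``) or ``OTHER`` for non-GTPase partners.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import networkx as nx

SUBFAMILIES = ("RHO", "RAS", "RAB", "ARF", "RAN", "RGK")
OTHER = "OTHER"

_TSV_HEADER_HINTS = {"protein_a", "protein_b", "source", "target", "score",
                     "confidence", "evidence", "node_a", "node_b"}


class EdgeTableError(ValueError):
    """Raised for malformed edge-table rows; message names the line number."""


@dataclass(frozen=True)
class InteractionRecord:
    """One curated edge: two gene symbols, a confidence score, an evidence tag."""

    source_symbol: str
    target_symbol: str
    confidence: float = 1.0
    evidence_tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "source_symbol", self.source_symbol.strip().upper())
        object.__setattr__(self, "target_symbol", self.target_symbol.strip().upper())
        if not self.source_symbol or not self.target_symbol:
            raise ValueError("gene symbols must be non-empty")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence!r} outside [0, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered pair in lexicographic canonical order."""
        a, b = self.source_symbol, self.target_symbol
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ProteinNode:
    symbol: str
    subfamily: str = OTHER
    is_gtpase: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbol", self.symbol.strip().upper())
        object.__setattr__(self, "subfamily", self.subfamily.strip().upper())
        if (self.subfamily == OTHER) == self.is_gtpase:
            raise ValueError(
                f"{self.symbol}: subfamily must be OTHER exactly when is_gtpase is False"
            )
        if self.is_gtpase and self.subfamily not in SUBFAMILIES:
            raise ValueError(f"unknown subfamily {self.subfamily!r}")


@dataclass(frozen=True)
class ConfidenceSummary:
    n: int
    mean: float
    sd: float
    bin_counts: Mapping[tuple[float, float], int]


@dataclass(frozen=True)
class CurationStats:
    n_considered: int
    n_unsupported: int

    @property
    def pct_confirmed(self) -> float:
        return 100.0 * (self.n_considered - self.n_unsupported) / self.n_considered


def _as_lines(stream: str | TextIO | Iterable[str]) -> Iterable[str]:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def _looks_like_header(fields: Sequence[str]) -> bool:
    lowered = {f.strip().lower() for f in fields}
    if lowered & _TSV_HEADER_HINTS:
        return True
    if len(fields) >= 3:
        try:
            float(fields[2])
        except ValueError:
            return True
    return False


def parse_edge_table(stream: str | TextIO | Iterable[str],
                     dialect: str = "tsv") -> list[InteractionRecord]:
    """Parse a TSV or SIF edge table into interaction records.

    TSV columns: protein_a, protein_b, score, evidence (header optional,
    auto-detected).  SIF rows ``A relation B [C ...]`` fan out to pairwise
    edges with confidence 1.0 and the relation stored as the evidence tag.
    Symbols are uppercased and stripped; row order is preserved.
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[InteractionRecord] = []
    lines = _as_lines(stream)
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if dialect == "tsv":
            fields = line.split("\t")
            if lineno == 1 and not records and _looks_like_header(fields):
                continue
            if len(fields) < 2:
                raise EdgeTableError(f"line {lineno}: expected >= 2 tab-separated fields")
            conf = 1.0
            if len(fields) >= 3 and fields[2].strip():
                try:
                    conf = float(fields[2])
                except ValueError as exc:
                    raise EdgeTableError(f"line {lineno}: bad confidence {fields[2]!r}") from exc
            evidence = fields[3].strip() if len(fields) >= 4 else ""
            try:
                records.append(InteractionRecord(fields[0], fields[1], conf, evidence))
            except ValueError as exc:
                raise EdgeTableError(f"line {lineno}: {exc}") from exc
        else:  # sif: whitespace- or tab-delimited fan-out rows
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise EdgeTableError(f"line {lineno}: SIF row needs nodeA, relation, nodeB")
            a, relation, targets = fields[0], fields[1], fields[2:]
            for b in targets:
                try:
                    records.append(InteractionRecord(a, b, 1.0, relation))
                except ValueError as exc:
                    raise EdgeTableError(f"line {lineno}: {exc}") from exc
    return records


def write_edge_table(records: Iterable[InteractionRecord], stream: TextIO,
                     dialect: str = "tsv", header: bool = True) -> None:
    """Write records in the given dialect (inverse of :func:`parse_edge_table`)."""
    if dialect == "tsv":
        if header:
            stream.write("protein_a\tprotein_b\tscore\tevidence\n")
        for r in records:
            stream.write(f"{r.source_symbol}\t{r.target_symbol}\t"
                         f"{r.confidence!r}\t{r.evidence_tag}\n")
    elif dialect == "sif":
        for r in records:
            tag = r.evidence_tag or "pp"
            stream.write(f"{r.source_symbol}\t{tag}\t{r.target_symbol}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def filter_by_confidence(records: Sequence[InteractionRecord],
                         threshold: float = 0.4) -> list[InteractionRecord]:
    """Keep records with confidence >= threshold (inclusive); order preserved."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return [r for r in records if r.confidence >= threshold]


def read_annotations(stream: str | TextIO | Iterable[str]) -> dict[str, ProteinNode]:
    """Read a two-column TSV (symbol, subfamily) into a symbol -> node mapping."""
    nodes: dict[str, ProteinNode] = {}
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if lineno == 1 and fields[0].strip().lower() in ("symbol", "gene", "protein"):
            continue
        if len(fields) < 2:
            raise EdgeTableError(f"line {lineno}: expected symbol and subfamily")
        sub = fields[1].strip().upper()
        node = ProteinNode(fields[0], sub, is_gtpase=(sub != OTHER))
        nodes[node.symbol] = node
    return nodes


def _node_attrs(node: ProteinNode) -> dict:
    return {"subfamily": node.subfamily, "is_gtpase": node.is_gtpase}


def build_network(records: Iterable[InteractionRecord],
                  annotations: Mapping[str, ProteinNode] | None = None) -> nx.Graph:
    """Build an undirected simple graph: self-loops dropped, duplicates collapsed.

    Unannotated symbols become ``OTHER`` nodes.  Annotated symbols absent from
    the records are kept as zero-degree nodes (the curated seed lists report
    GTPases with no validated partners as network members without links).
    """
    annotations = annotations or {}
    g = nx.Graph()
    for symbol, node in annotations.items():
        g.add_node(symbol, **_node_attrs(node))
    for r in records:
        if r.source_symbol == r.target_symbol:
            continue
        for s in (r.source_symbol, r.target_symbol):
            if s not in g:
                g.add_node(s, subfamily=OTHER, is_gtpase=False)
        a, b = r.pair
        if g.has_edge(a, b):
            # keep the strongest supporting score for the collapsed edge
            if r.confidence > g[a][b].get("confidence", 0.0):
                g[a][b]["confidence"] = r.confidence
                g[a][b]["evidence"] = r.evidence_tag
        else:
            g.add_edge(a, b, confidence=r.confidence, evidence=r.evidence_tag)
    return g


def union(networks: Sequence[nx.Graph]) -> nx.Graph:
    """Graph union: node and edge sets merged; conflicting subfamily labels error."""
    if not networks:
        raise ValueError("union requires at least one network")
    out = nx.Graph()
    for g in networks:
        for n, attrs in g.nodes(data=True):
            if n in out:
                old = out.nodes[n].get("subfamily", OTHER)
                new = attrs.get("subfamily", OTHER)
                if old != new:
                    raise ValueError(f"{n}: conflicting subfamily labels {old!r} vs {new!r}")
            else:
                out.add_node(n, **attrs)
        for a, b, attrs in g.edges(data=True):
            if not out.has_edge(a, b):
                out.add_edge(a, b, **attrs)
    return out


def exclude_edges(network: nx.Graph,
                  blacklist: Iterable[tuple[str, str]]) -> nx.Graph:
    """Remove the listed unordered pairs if present; everything else untouched."""
    out = network.copy()
    for a, b in blacklist:
        a, b = a.strip().upper(), b.strip().upper()
        if out.has_edge(a, b):
            out.remove_edge(a, b)
    return out


def canonical_edges(network: nx.Graph) -> list[tuple[str, str]]:
    """Edge list in lexicographic canonical order (deterministic output)."""
    return sorted(tuple(sorted(map(str, e))) for e in network.edges())


def confidence_summary(records: Sequence[InteractionRecord],
                       bin_width: float = 0.1) -> ConfidenceSummary:
    """Population mean/SD and half-open histogram bins ``[x, x+w)``, last closed at 1."""
    if not records:
        raise ValueError("confidence_summary requires at least one record")
    scores = [r.confidence for r in records]
    n = len(scores)
    mean = sum(scores) / n
    sd = math.sqrt(sum((s - mean) ** 2 for s in scores) / n)
    n_bins = math.ceil(round(1.0 / bin_width, 9))
    bins: dict[tuple[float, float], int] = {}
    for i in range(n_bins):
        lo = round(i * bin_width, 9)
        hi = round(min((i + 1) * bin_width, 1.0), 9)
        bins[(lo, hi)] = 0
    for s in scores:
        idx = min(int(s / bin_width), n_bins - 1)
        lo = round(idx * bin_width, 9)
        hi = round(min((idx + 1) * bin_width, 1.0), 9)
        bins[(lo, hi)] += 1
    return ConfidenceSummary(n=n, mean=mean, sd=sd, bin_counts=bins)


def curation_report(n_considered: int, n_unsupported: int) -> CurationStats:
    """Literature-validation arithmetic: share of edges confirmed positive."""
    if n_considered <= 0:
        raise ValueError("n_considered must be positive")
    if not (0 <= n_unsupported <= n_considered):
        raise ValueError("n_unsupported must lie in [0, n_considered]")
    return CurationStats(n_considered=n_considered, n_unsupported=n_unsupported)
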