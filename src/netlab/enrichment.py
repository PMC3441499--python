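"""Over-representation testing of gene lists against annotation tables.

One-sided upper-tail hypergeometric (Fisher's exact) p values per term, plus
the EASE variant which removes one gene from the overlap before computing the
tail — a conservative penalty against single-gene terms.  Annotation content
(pathway/domain tables) is user-supplied; nothing is bundled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationTable:
    terms: Mapping[str, frozenset]
    background: frozenset

    def __post_init__(self) -> None:
        if not self.background:
            raise ValueError("background gene set must be non-empty")
        for term, genes in self.terms.items():
            if not genes <= self.background:
                raise ValueError(f"term {term!r} has genes outside the background")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]],
                   background: Iterable[str] | None = None) -> "AnnotationTable":
        """Build from (term, gene) pairs; background defaults to all annotated genes."""
        terms: dict[str, set] = {}
        for term, gene in pairs:
            terms.setdefault(term.strip(), set()).add(gene.strip().upper())
        frozen = {t: frozenset(g) for t, g in terms.items()}
        if background is None:
            bg = frozenset().union(*frozen.values()) if frozen else frozenset()
        else:
            bg = frozenset(g.strip().upper() for g in background)
        return cls(terms=frozen, background=bg)

    @classmethod
    def from_tsv(cls, stream: TextIO | Iterable[str],
                 background: Iterable[str] | None = None) -> "AnnotationTable":
        pairs = []
        for line in stream:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"annotation row needs term and gene: {line!r}")
            pairs.append((fields[0], fields[1]))
        return cls.from_pairs(pairs, background)

    @classmethod
    def from_gmt(cls, stream: TextIO | Iterable[str],
                 background: Iterable[str] | None = None) -> "AnnotationTable":
        pairs = []
        for line in stream:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            term = fields[0]
            pairs.extend((term, g) for g in fields[2:] if g)
        return cls.from_pairs(pairs, background)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int          # overlap
    n: int          # query size (within background)
    K: int          # term size
    N: int          # background size
    p_fisher: float
    p_ease: float


def _upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), clamped into (0, 1]."""
    if k <= 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 5e-324), 1.0)


def fisher_enrichment(query: Iterable[str],
                      table: AnnotationTable) -> list[EnrichmentResult]:
    """One result per term; query genes outside the background are dropped."""
    q = {g.strip().upper() for g in query}
    dropped = q - table.background
    if dropped:
        logger.info("dropping %d query genes outside the background", len(dropped))
    q &= table.background
    N, n = len(table.background), len(q)
    results = []
    for term in sorted(table.terms):
        genes = table.terms[term]
        k = len(q & genes)
        results.append(EnrichmentResult(
            term=term, k=k, n=n, K=len(genes), N=N,
            p_fisher=_upper_tail(k, N, len(genes), n),
            p_ease=_upper_tail(k - 1, N, len(genes), n),
        ))
    return results


def benjamini_hochberg(results: Sequence[EnrichmentResult],
                       stat: str = "fisher") -> dict[str, float]:
    """Optional FDR adjustment (term -> q value); not applied by default."""
    from statsmodels.stats.multitest import multipletests

    ps = [getattr(r, f"p_{stat}") for r in results]
    if not ps:
        return {}
    _, q, _, _ = multipletests(ps, method="fdr_bh")
    return {r.term: float(qi) for r, qi in zip(results, q)}


def filter_significant(results: Sequence[EnrichmentResult], alpha: float = 0.05,
                       stat: str = "fisher") -> list[EnrichmentResult]:
    """Keep results with the selected p <= alpha (inclusive), sorted ascending."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    if stat not in ("fisher", "ease"):
        raise ValueError(f"unknown stat {stat!r}")
    key = f"p_{stat}"
    kept = [r for r in results if getattr(r, key) <= alpha]
    kept.sort(key=lambda r: (getattr(r, key), r.term))
    return kept
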