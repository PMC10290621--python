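"""Local over-representation analysis of gene sets against GMT libraries.

Replaces a web enrichment service with the core statistic: for each library
term, a one-sided hypergeometric upper-tail test of the overlap between a
query gene set and the term within a finite gene universe, followed by
Benjamini–Hochberg adjustment across the library's terms. Gene symbols are
case-folded to upper case throughout; no ortholog mapping is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ParseError

__all__ = [
    "GeneSetLibrary",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "fisher_enrich",
    "bh_adjust",
    "rank_terms",
]


def _norm(genes: Iterable[str]) -> frozenset[str]:
    return frozenset(str(g).upper() for g in genes)


@dataclass
class GeneSetLibrary:
    """A named collection of gene sets (term -> member genes, uppercased)."""

    name: str
    terms: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ParseError(f"term {term!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.terms)

    def gene_universe(self) -> frozenset[str]:
        return frozenset(g for genes in self.terms.values() for g in genes)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    overlap: int  # k
    term_size: int  # K (within universe)
    query_size: int  # n
    universe_size: int  # N
    p_value: float
    p_adjusted: float
    overlapping_genes: tuple[str, ...]

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_value)


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Parse a GMT file: tab-separated term, description, member genes.

    Duplicate genes within a set are deduplicated (first occurrence kept);
    an empty description field is tolerated.
    """
    path = Path(path)
    terms: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            term, desc, *genes = fields
            if term in terms:
                raise ParseError(f"{path}: line {lineno}: duplicate term {term!r}")
            deduped = tuple(dict.fromkeys(g.upper() for g in genes if g.strip()))
            if not deduped:
                raise ParseError(f"{path}: line {lineno}: term {term!r} has no genes")
            terms[term] = deduped
            descriptions[term] = desc
    return GeneSetLibrary(name=path.stem, terms=terms, descriptions=descriptions)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in library.terms.items():
            desc = (library.descriptions or {}).get(term, "")
            fh.write("\t".join([term, desc, *genes]) + "\n")


def fisher_enrich(
    query: Iterable[str],
    library: GeneSetLibrary,
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation of ``query`` per term.

    p = P(X >= k) with X ~ Hypergeom(N, K, n) where N is the universe size,
    K the term size within the universe, n the query size, k the overlap.
    Terms with zero overlap are still reported (p = 1). BH-adjusted p-values
    are computed across all terms of the library.
    """
    q = _norm(query)
    u = _norm(universe)
    if not q:
        raise ConfigError("query gene set is empty")
    if not u:
        raise ConfigError("gene universe is empty")
    if not q <= u:
        raise ConfigError(
            f"query genes outside the universe: {sorted(q - u)[:5]}"
        )
    if not library.terms:
        return []
    results = []
    N, n = len(u), len(q)
    for term, genes in library.terms.items():
        members = _norm(genes) & u
        overlap = tuple(sorted(q & members))
        k, K = len(overlap), len(members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, 0.0), 1.0) or np.nextafter(0, 1)
        results.append((term, k, K, overlap, p))
    adjusted = bh_adjust([r[4] for r in results])
    return [
        EnrichmentResult(
            term=term,
            overlap=k,
            term_size=K,
            query_size=n,
            universe_size=N,
            p_value=p,
            p_adjusted=adj,
            overlapping_genes=overlap,
        )
        for (term, k, K, overlap, p), adj in zip(results, adjusted)
    ]


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        bad = p[(p <= 0) | (p > 1) | ~np.isfinite(p)][0]
        raise ConfigError(f"p-values must lie in (0, 1]; got {bad}")
    return list(multipletests(p, method="fdr_bh")[1])


def rank_terms(results: Sequence[EnrichmentResult], top: int = 10) -> list[EnrichmentResult]:
    """Top terms by ascending p; ties broken by larger overlap, then term name."""
    ordered = sorted(results, key=lambda r: (r.p_value, -r.overlap, r.term))
    return ordered[: max(top, 0)]


def results_to_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "term": [r.term for r in results],
            "k": [r.overlap for r in results],
            "K": [r.term_size for r in results],
            "n": [r.query_size for r in results],
            "N": [r.universe_size for r in results],
            "p": [r.p_value for r in results],
            "p_adj": [r.p_adjusted for r in results],
            "genes": [",".join(r.overlapping_genes) for r in results],
        }
    ).to_csv(path, sep="\t", index=False)
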