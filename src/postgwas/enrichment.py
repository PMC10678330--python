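"""Over-representation analysis of a gene set against GMT-style libraries.

The test statistic is the one-sided hypergeometric upper tail
``P[X >= k]`` for ``X ~ Hypergeometric(N, K, n)`` — equivalent to a
one-sided Fisher exact test on the 2x2 overlap table, the core p-value of
the usual web enrichment services.  P-values are adjusted per library with
the Benjamini-Hochberg step-up procedure, and a term is called significant
when its adjusted p-value is strictly below alpha *and* the overlap
involves more than three genes (>= 4).

The universe defaults to the genes annotated in the library, not the
genome; pass an explicit universe to override.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError

__all__ = [
    "GeneSetTerm",
    "GeneSetLibrary",
    "EnrichmentRecord",
    "hypergeometric_pvalue",
    "bh_adjust",
    "run_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetTerm:
    term_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"term {self.term_id!r} has no member genes")


@dataclass(frozen=True)
class GeneSetLibrary:
    """A named collection of gene sets plus the annotation universe."""

    terms: dict[str, GeneSetTerm]
    universe: frozenset[str] | None = None

    def __post_init__(self):
        if self.universe is not None:
            for t in self.terms.values():
                if not t.genes <= self.universe:
                    raise ValidationError(
                        f"term {t.term_id!r} has members outside the universe"
                    )

    def effective_universe(self) -> frozenset[str]:
        if self.universe is not None:
            return self.universe
        out: set[str] = set()
        for t in self.terms.values():
            out |= t.genes
        return frozenset(out)


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    term_name: str
    overlap_k: int
    term_size_K: int
    query_size_n: int
    universe_size_N: int
    p: float
    adj_p: float
    overlap_genes: frozenset[str]
    significant: bool


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability ``P[X >= k]``, ``X ~ Hypergeometric(N, K, n)``.

    ``N`` is the universe size, ``K`` the term size, ``n`` the query size
    and ``k`` the observed overlap.  Computed through scipy's log-gamma
    based survival function.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name} must be a non-negative integer, got {v}")
    if K > N or n > N:
        raise ValidationError(f"require K <= N and n <= N (K={K}, n={n}, N={N})")
    if k > min(K, n):
        raise ValidationError(f"overlap k={k} exceeds min(K, n)={min(K, n)}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise ValidationError("p-values must be finite and in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def run_enrichment(
    query: set[str],
    lib: GeneSetLibrary,
    alpha: float = 0.05,
    min_overlap: int = 4,
) -> list[EnrichmentRecord]:
    """One-sided hypergeometric ORA of ``query`` against every library term.

    Query genes outside the universe are dropped (logged).  Records are
    sorted by (adjusted p, term id); the ``significant`` flag requires
    ``adj_p < alpha`` and ``overlap_k >= min_overlap``.
    """
    if not lib.terms:
        raise ValidationError("gene-set library is empty")
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    universe = lib.effective_universe()
    inside = {g for g in query if g in universe}
    dropped = len(query) - len(inside)
    if dropped:
        logger.info("dropped %d query genes outside the universe", dropped)
    N, n = len(universe), len(inside)

    term_ids = sorted(lib.terms)
    raw = []
    overlaps = []
    for tid in term_ids:
        term = lib.terms[tid]
        ov = inside & term.genes
        overlaps.append(ov)
        raw.append(hypergeometric_pvalue(len(ov), len(term.genes), n, N))
    adj = bh_adjust(raw)

    records = [
        EnrichmentRecord(
            term_id=tid,
            term_name=lib.terms[tid].name,
            overlap_k=len(ov),
            term_size_K=len(lib.terms[tid].genes),
            query_size_n=n,
            universe_size_N=N,
            p=p,
            adj_p=float(a),
            overlap_genes=frozenset(ov),
            significant=bool(a < alpha and len(ov) >= min_overlap),
        )
        for tid, ov, p, a in zip(term_ids, overlaps, raw, adj)
    ]
    records.sort(key=lambda r: (r.adj_p, r.term_id))
    return records
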