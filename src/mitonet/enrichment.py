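"""Hypergeometric overrepresentation analysis with BH-FDR and strength.

A query node set (an MCL cluster, or the whole differential network) is
tested term-by-term against an annotation collection: with a universe of N
identifiers of which K carry the term, and a query of n universe members
of which k carry it, the p-value is the exact upper hypergeometric tail
P[X >= k].  "Strength" is the STRING-style effect size
log10((k/n) / (K/N)), i.e. the log10 ratio of observed to expected term
frequency.  FDR is Benjamini–Hochberg across all tested terms.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotationCollection, ValidationError

__all__ = [
    "EnrichmentRow",
    "EnrichmentResult",
    "hypergeom_test",
    "bh_fdr",
    "enrich",
]


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's overrepresentation statistics for one query set."""

    term_id: str
    description: str
    k: int  # query members annotated to the term
    n: int  # query size (universe members only)
    K: int  # universe members annotated to the term
    N: int  # universe size
    strength: float
    p_value: float
    fdr: float

    def __post_init__(self):
        if not (0 <= self.k <= min(self.n, self.K) and self.K <= self.N and self.n <= self.N):
            raise ValidationError(
                f"inconsistent counts k={self.k}, n={self.n}, K={self.K}, N={self.N}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    """Rows sorted by (p, term id) plus the count of dropped query members."""

    rows: tuple[EnrichmentRow, ...]
    n_query_outside_universe: int = 0

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)

    def __getitem__(self, i):
        return self.rows[i]


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P[X >= k].

    X counts annotated members in a size-n draw (without replacement) from
    a universe of N identifiers of which K are annotated.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValidationError(f"need 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
    # survival function is P[X > k-1] = P[X >= k]
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query_set: Iterable,
    annotations: AnnotationCollection,
    universe: Iterable,
) -> EnrichmentResult:
    """Overrepresentation of ``query_set`` in each annotation term.

    Query members outside the universe are dropped (their count is
    reported on the result); terms with no universe members are skipped so
    the BH family size stays meaningful.  Rows come back sorted by p-value
    then term id.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValidationError("universe is empty")
    query = frozenset(query_set)
    effective = query & universe
    dropped = len(query) - len(effective)
    if not effective:
        raise ValidationError("query set has no members in the universe")
    n, N = len(effective), len(universe)

    tested: list[tuple[str, str, int, int, float, float]] = []
    for term in annotations:
        desc, members = annotations.terms[term]
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(effective & in_universe)
        p = hypergeom_test(k, K, n, N)
        with np.errstate(divide="ignore"):
            strength = float(np.log10((k / n) / (K / N))) if k else float("-inf")
        tested.append((term, desc, k, K, strength, p))

    fdrs = bh_fdr([t[5] for t in tested])
    rows = [
        EnrichmentRow(
            term_id=term,
            description=desc,
            k=k,
            n=n,
            K=K,
            N=N,
            strength=strength,
            p_value=p,
            fdr=float(fdr),
        )
        for (term, desc, k, K, strength, p), fdr in zip(tested, fdrs)
    ]
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return EnrichmentResult(rows=tuple(rows), n_query_outside_universe=dropped)
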