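"""Gene-set enrichment mathematics.

Three primitives drive every enrichment step in the package:

* ``hypergeom_overlap_test`` — the upper-tail hypergeometric (one-sided
  Fisher) probability of the observed overlap between a query and a term
  within a finite background, plus a Haldane-corrected odds ratio.
* ``ranked_hypergeometric`` — the ordered variant: the query is a ranked
  gene list and the reported p-value is the *minimum* hypergeometric tail
  over all prefixes of the ranking, together with the minimising depth and
  the overlapping genes at that depth. The minimum is used raw; multiple
  testing is handled across terms (BH), not across depths.
* ``empirical_brown_fuse`` — Brown's extension of Fisher's method for
  combining dependent p-value channels. Each channel's values are mapped
  through w = -2 ln(ECDF) (right-continuous, so the smallest value maps to
  1/n, avoiding log 0); the per-item channel sum is referred to a scaled
  chi-square whose degrees of freedom and scale come from the empirical
  variance of the channel sums. Under independent uniform channels this
  reduces to Fisher's method; with a single channel it is the identity.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .core import GeneSet, GeneSetDB, bh_fdr

__all__ = [
    "EnrichmentHit",
    "hypergeom_overlap_test",
    "ranked_hypergeometric",
    "empirical_brown_fuse",
    "enrich_list_against_db",
]


@dataclasses.dataclass
class EnrichmentHit:
    term_id: str
    pvalue: float
    fdr: float = np.nan
    best_rank_depth: int = 0
    overlap_genes: list = dataclasses.field(default_factory=list)


def hypergeom_overlap_test(k: int, K: int, n: int, N: int):
    """P(X >= k) for overlap k between a size-K set and a size-n draw from N.

    Returns ``(pvalue, odds_ratio)``; the odds ratio comes from the 2x2
    table (k, n-k, K-k, N-n-K+k) with the Haldane 0.5 continuity
    correction whenever any cell is zero.
    """
    if not (0 <= k <= min(K, n) <= N):
        raise ValueError(f"inconsistent overlap table k={k} K={K} n={n} N={N}")
    d = N - n - K + k
    if d < 0:
        raise ValueError(f"inconsistent overlap table k={k} K={K} n={n} N={N}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    a, b, c = k, n - k, K - k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return min(p, 1.0), (a * d) / (b * c)


def ranked_hypergeometric(
    query, term: "GeneSet | frozenset", background
) -> EnrichmentHit:
    """Minimum hypergeometric tail over all prefixes of a ranked query.

    ``query`` is an ordered gene list (most significant first) drawn from
    ``background``; the term is intersected with the background before
    testing, so genes never detected do not inflate the set size. Ties in
    the minimum are broken toward the smallest depth.
    """
    term_id = term.id if isinstance(term, GeneSet) else ""
    term_genes = term.genes if isinstance(term, GeneSet) else frozenset(term)
    bg = frozenset(background)
    term_genes = term_genes & bg
    query = [g for g in query if g in bg]
    if not query or not term_genes:
        return EnrichmentHit(term_id=term_id, pvalue=1.0)
    N = len(bg)
    K = len(term_genes)
    hits = np.fromiter((g in term_genes for g in query), dtype=int)
    k_at_depth = np.cumsum(hits)
    depths = np.arange(1, len(query) + 1)
    pvals = stats.hypergeom.sf(k_at_depth - 1, N, K, depths)
    best = int(np.argmin(pvals))  # argmin takes the first (smallest depth)
    depth = best + 1
    overlap = [g for g in query[:depth] if g in term_genes]
    return EnrichmentHit(
        term_id=term_id,
        pvalue=float(min(pvals[best], 1.0)),
        best_rank_depth=depth,
        overlap_genes=overlap,
    )


def empirical_brown_fuse(P) -> np.ndarray:
    """Fuse dependent p-value channels with the empirical Brown method.

    ``P`` is items x channels with values in (0, 1]. Each channel c is
    transformed to w_c = -2 ln(ECDF_c), the per-item sums X_i = sum_c w_ic
    are referred to a chi-square with f = 2 E^2 / Var degrees of freedom and
    scale Var / (2E), where E = 2 m (m channels) and Var is the empirical
    variance of X (per-channel variances plus twice the covariances). A
    single channel passes through unchanged.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    n, m = P.shape
    if m == 0 or n == 0:
        raise ValueError("need at least one item and one channel")
    if (P <= 0).any() or (P > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if m == 1:
        return P[:, 0].copy()
    W = np.empty_like(P)
    for c in range(m):
        col = P[:, c]
        # right-continuous ECDF: fraction of values <= p; min maps to >= 1/n,
        # ties share the largest rank among equals
        sorted_col = np.sort(col, kind="mergesort")
        ecdf = np.searchsorted(sorted_col, col, side="right") / n
        W[:, c] = -2.0 * np.log(ecdf)
    X = W.sum(axis=1)
    E = 2.0 * m
    if n < 2:
        var = 4.0 * m  # no data to estimate covariance; Fisher fallback
    else:
        cov = np.cov(W, rowvar=False)
        var = float(np.sum(cov))
    if var <= 0:
        var = 4.0 * m
    f = 2.0 * E * E / var
    scale = var / (2.0 * E)
    fused = stats.chi2.sf(X / scale, df=f)
    return np.minimum(fused, 1.0)


def enrich_list_against_db(
    query,
    db: GeneSetDB,
    background,
    alpha: float = 0.05,
) -> list:
    """Ranked-hypergeometric enrichment of a query against every term.

    ``query`` is either a single ordered gene list or a list of ordered
    lists (one per p-value channel); with several channels the per-term
    channel p-values are fused with the empirical Brown method before the
    BH correction across terms. Hits come back sorted by FDR then p-value;
    ``alpha`` is recorded by callers as the significance mark, every term
    is returned regardless.
    """
    if len(db) == 0:
        return []
    channels = (
        [query]
        if query and isinstance(query[0], str)
        else [list(q) for q in query]
    )
    if not channels or all(len(q) == 0 for q in channels):
        hits = [EnrichmentHit(term_id=s.id, pvalue=1.0, fdr=1.0) for s in db]
        return hits
    per_term = []
    for s in db:
        chan_hits = [ranked_hypergeometric(q, s, background) for q in channels]
        per_term.append(chan_hits)
    if len(channels) == 1:
        pvals = np.array([h[0].pvalue for h in per_term])
        best = [h[0] for h in per_term]
    else:
        P = np.array([[h.pvalue for h in hs] for hs in per_term])
        # chi2.sf can underflow to 0 for overwhelming signals; keep in (0,1]
        pvals = np.maximum(empirical_brown_fuse(np.clip(P, 1e-300, 1.0)), 1e-300)
        # report depth/overlap from the most significant channel
        best = [hs[int(np.argmin([h.pvalue for h in hs]))] for hs in per_term]
    fdrs = bh_fdr(np.minimum(pvals, 1.0))
    hits = [
        EnrichmentHit(
            term_id=s.id,
            pvalue=float(pvals[i]),
            fdr=float(fdrs[i]),
            best_rank_depth=best[i].best_rank_depth,
            overlap_genes=best[i].overlap_genes,
        )
        for i, s in enumerate(db)
    ]
    hits.sort(key=lambda h: (h.fdr, h.pvalue, h.term_id))
    return hits
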