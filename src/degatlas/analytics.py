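"""Compendium-level structure: clustering, DE-prior, cluster annotation.

Comparisons are related through the correlation of their per-gene
FDR-adjusted p-values: for each pair, over the genes DE in at least one of
the two and detected in both, the squared Pearson correlation r^2 enters a
symmetric comparison-by-comparison matrix. Hierarchical clustering
(Ward.D2 on the Euclidean distances between rows of |r|) cut at a fixed
height groups comparisons by shared differential signal; the median
within-cluster fraction of shared DEGs quantifies how homogeneous each
cluster is, and clusters are annotated by fusing the member comparisons'
per-gene FDR vectors with the empirical Brown method before a
ranked-hypergeometric gene-set enrichment.

The DE prior scores each gene by how often it is differentially expressed
relative to how often it is detected; two priors are compared with
hypergeometric overlap tests of their top-q gene sets at cumulative
percentile increments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .core import Compendium, GeneSetDB, bh_fdr
from .enrichment import (
    empirical_brown_fuse,
    enrich_list_against_db,
    hypergeom_overlap_test,
)

__all__ = [
    "pairwise_comparison_correlation",
    "cluster_comparisons",
    "median_cluster_overlap",
    "annotate_clusters",
    "de_prior",
    "prior_overlap_curve",
]


def pairwise_comparison_correlation(c: Compendium) -> pd.DataFrame:
    """Squared Pearson correlations of FDR vectors between comparison pairs.

    For each pair, the gene universe is genes DE in at least one of the two
    comparisons and detected in both; entries with fewer than three
    co-usable genes or a constant vector are missing. The diagonal is 1.
    """
    if len(c) < 2:
        raise ValueError("need at least two comparisons")
    comps = list(c)
    ids = [x.id for x in comps]
    fdr = [x.fdr_series() for x in comps]
    degs = [x.deg_genes() for x in comps]
    detected = [x.detected_genes for x in comps]
    n = len(comps)
    M = np.full((n, n), np.nan)
    np.fill_diagonal(M, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            uni = (degs[i] | degs[j]) & detected[i] & detected[j]
            uni = sorted(uni & set(fdr[i].index) & set(fdr[j].index))
            if len(uni) < 3:
                continue
            a = fdr[i].loc[uni].to_numpy(dtype=float)
            b = fdr[j].loc[uni].to_numpy(dtype=float)
            if np.ptp(a) == 0 or np.ptp(b) == 0 or np.isnan(a).any() or np.isnan(b).any():
                continue
            r = np.corrcoef(a, b)[0, 1]
            M[i, j] = M[j, i] = r * r
    return pd.DataFrame(M, index=ids, columns=ids)


def cluster_comparisons(
    M: pd.DataFrame,
    height: float = 30.0,
    n_clusters: int | None = None,
    on: str = "abs_r",
) -> pd.Series:
    """Ward.D2 clustering of the comparison correlation matrix.

    Rows of |r| (= sqrt(r^2); ``on="r2"`` clusters the squared values
    instead) are embedded by their Euclidean distances and agglomerated
    with Ward's criterion; flat clusters come from cutting the dendrogram
    at ``height`` (or into ``n_clusters``). Missing similarities are
    imputed as 0 — the most conservative choice. Labels are 1..K in order
    of first appearance.
    """
    ids = list(M.index)
    if len(ids) < 2:
        return pd.Series([1] * len(ids), index=ids, dtype=int)
    V = M.to_numpy(dtype=float).copy()
    V[np.isnan(V)] = 0.0
    if on == "abs_r":
        V = np.sqrt(np.clip(V, 0.0, None))
    elif on != "r2":
        raise ValueError(f"unknown matrix transform {on!r}")
    D = pdist(V, metric="euclidean")
    Z = linkage(D, method="ward")  # Ward.D2: Ward on distances
    if n_clusters is not None:
        raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        raw = fcluster(Z, t=height, criterion="distance")
    # relabel 1..K in order of first appearance for stable output
    seen: dict = {}
    labels = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in seen:
            seen[lab] = len(seen) + 1
        labels[i] = seen[lab]
    return pd.Series(labels, index=ids, dtype=int)


def median_cluster_overlap(c: Compendium, labels: pd.Series) -> pd.Series:
    """Median within-cluster DEG sharing.

    For ordered pairs (i, j), i != j, within a cluster the share is
    |DEG_i ∩ DEG_j| / |DEG_i|; the median over pairs summarises how much of
    a typical comparison's DEG list recurs inside its cluster. Singleton
    clusters are missing.
    """
    degs = {comp.id: comp.deg_genes() for comp in c}
    out = {}
    for lab in sorted(labels.unique()):
        members = list(labels.index[labels == lab])
        if len(members) < 2:
            out[lab] = np.nan
            continue
        shares = []
        for i in members:
            for j in members:
                if i == j:
                    continue
                di = degs[i]
                shares.append(len(di & degs[j]) / len(di) if di else np.nan)
        out[lab] = float(np.nanmedian(shares)) if shares else np.nan
    return pd.Series(out, name="median_deg_overlap")


def annotate_clusters(
    c: Compendium, labels: pd.Series, db: GeneSetDB, alpha: float = 0.05
) -> dict:
    """Gene-set annotation of each cluster via Brown-fused FDR vectors.

    Member comparisons' per-gene FDR vectors are the fusion channels (a
    gene missing from a member contributes p = 1); the genes ranked by
    fused p-value form the query for a ranked-hypergeometric enrichment
    against ``db`` over the cluster's detected-gene union.
    """
    out = {}
    for lab in sorted(labels.unique()):
        members = [c[i] for i in labels.index[labels == lab]]
        bg = frozenset().union(*(m.detected_genes for m in members))
        genes = sorted(bg)
        pos = {g: i for i, g in enumerate(genes)}
        P = np.ones((len(genes), len(members)))
        for k, m in enumerate(members):
            fdr = m.fdr_series()
            shared = [g for g in genes if g in fdr.index]
            vals = fdr.loc[shared].to_numpy(dtype=float)
            vals = np.clip(np.nan_to_num(vals, nan=1.0), 1e-300, 1.0)
            P[[pos[g] for g in shared], k] = vals
        fused = empirical_brown_fuse(P)
        order = np.argsort(fused, kind="mergesort")
        ranked = [genes[i] for i in order]
        out[lab] = enrich_list_against_db(ranked, db, bg, alpha)
    return out


def de_prior(c: Compendium) -> pd.DataFrame:
    """Per-gene DE frequency: #comparisons DE / #comparisons detected.

    Returns a DataFrame indexed by gene with ``de_frequency`` and a dense
    1-based ``rank`` (1 = most frequently DE; ties broken lexicographically).
    """
    if len(c) == 0:
        raise ValueError("compendium is empty")
    n_de: dict = {}
    n_det: dict = {}
    for comp in c:
        degs = comp.deg_genes()
        for g in comp.detected_genes:
            n_det[g] = n_det.get(g, 0) + 1
        for g in degs:
            n_de[g] = n_de.get(g, 0) + 1
    genes = sorted(n_det)
    freq = np.array([n_de.get(g, 0) / n_det[g] for g in genes])
    df = pd.DataFrame({"de_frequency": freq}, index=pd.Index(genes, name="gene"))
    df = df.sort_values(
        "de_frequency", ascending=False, kind="mergesort"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def prior_overlap_curve(
    a: pd.DataFrame, b: pd.DataFrame, step: float = 0.01
) -> pd.DataFrame:
    """Overlap of two DE priors' top-q gene sets at percentile increments.

    At each cumulative fraction q in {step, 2·step, ..., 1} the top-q genes
    of each prior (by rank) are intersected and tested with the
    hypergeometric overlap test within the shared universe; p-values are
    BH-corrected across increments. The q = 1 increment is degenerate (both
    sets equal the universe) and reported with a missing odds ratio.
    """
    shared = sorted(set(a.index) & set(b.index))
    if not shared:
        raise ValueError("priors share no genes")
    a = a.loc[shared].sort_values("rank")
    b = b.loc[shared].sort_values("rank")
    N = len(shared)
    rows = []
    qs = np.arange(step, 1 + step / 2, step)
    for q in qs:
        top = max(1, int(round(q * N)))
        sa = set(a.index[:top])
        sb = set(b.index[:top])
        k = len(sa & sb)
        if top >= N:
            rows.append(
                {"q": q, "odds_ratio": np.nan, "pvalue": 1.0, "n_overlap": k}
            )
            continue
        p, odds = hypergeom_overlap_test(k, top, top, N)
        rows.append({"q": q, "odds_ratio": odds, "pvalue": p, "n_overlap": k})
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["pvalue"])
    return df
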