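"""Querying a user gene list against the compendium.

A query is a list of gene symbols, optionally with per-gene p-values and
coefficients (fold-changes, GWAS effect sizes, ...). Three input modes:

* ``full`` — genes + p-values + coefficients: every channel runs.
* ``ordered`` — genes ranked by significance but without statistics: the
  p-values are evenly spaced with the *least* significant set to 0.049
  (p_i = 0.049 i / n), the Pearson channel is disabled and the Spearman
  channel falls back to the rank order as a coefficient surrogate.
* ``unordered`` — a bare set of genes: every p-value is 0.049 and both
  correlation channels are disabled.

0.049 keeps synthesised p-values just under the conventional 0.05
significance mark so downstream thresholding treats every query gene as
significant without fabricating strong evidence.

``deet_enrich`` then reports, per compendium comparison, four channels:
ranked-hypergeometric enrichment of the query against each comparison's
DEG list (``deg_overlap``), hypergeometric overlap of the query's enriched
pathway / TF terms with each comparison's enriched terms
(``pathway_overlap`` / ``tf_overlap``), and Spearman / Pearson correlation
of the user coefficients with the comparison's log2 fold-changes on shared
DEGs — computed only within comparisons already enriched at the gene level.
Every channel is BH-corrected at alpha = 0.05 by default.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    Compendium,
    ComparisonRecord,
    GeneSet,
    GeneSetDB,
    bh_fdr,
    compendium_to_gmt,
    filter_gene_sets,
)
from .compendium import PATHWAY_SIZE_WINDOW, TF_SIZE_WINDOW
from .enrichment import (
    EnrichmentHit,
    enrich_list_against_db,
    hypergeom_overlap_test,
    ranked_hypergeometric,
)

logger = logging.getLogger(__name__)

__all__ = [
    "UserQuery",
    "EnrichmentReport",
    "prepare_user_input",
    "resolve_background",
    "deet_enrich",
    "enrich_genesonly",
    "correlate_with_comparison",
    "input_as_reference",
    "report_tables",
    "overlap_stats",
]

#: ceiling for synthesised p-values on ordered / unordered input
SYNTH_PVALUE = 0.049


@dataclasses.dataclass
class UserQuery:
    genes: list
    pvalues: np.ndarray
    coefficients: np.ndarray | None
    mode: str  # full | ordered | unordered
    background: frozenset | None = None

    def __post_init__(self):
        if self.mode not in ("full", "ordered", "unordered"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.pvalues) != len(self.genes):
            raise ValueError("p-values not aligned with genes")
        if self.mode == "full" and (
            self.coefficients is None
            or len(self.coefficients) != len(self.genes)
        ):
            raise ValueError("full mode requires aligned coefficients")

    def ranked_genes(self) -> list:
        """Genes by ascending p-value (stable in input order on ties)."""
        order = np.argsort(self.pvalues, kind="mergesort")
        return [self.genes[i] for i in order]

    def coefficient_series(self) -> pd.Series | None:
        """Per-gene coefficients; in ordered mode a rank surrogate.

        The surrogate is the negated 1-based rank, so more significant
        genes get larger values — only its ordering is ever used (Spearman).
        """
        if self.mode == "full":
            return pd.Series(self.coefficients, index=self.genes, dtype=float)
        if self.mode == "ordered":
            return pd.Series(
                -np.arange(1, len(self.genes) + 1, dtype=float),
                index=self.genes,
            )
        return None


@dataclasses.dataclass
class EnrichmentReport:
    """Per-comparison results across channels plus the user's own terms."""

    deg_overlap: pd.DataFrame
    pathway_overlap: pd.DataFrame
    tf_overlap: pd.DataFrame
    correlations: pd.DataFrame
    user_pathways: list
    user_tfs: list
    mode: str


def prepare_user_input(
    genes,
    pvalues=None,
    coefficients=None,
    collapse: str = "min_p",
    uppercase: bool = False,
) -> UserQuery:
    """Normalise raw user input into a :class:`UserQuery`.

    Duplicate symbols are collapsed by minimum p-value (``collapse="min_p"``,
    the default) or by first occurrence (``collapse="first"``).
    """
    genes = [str(g).upper() if uppercase else str(g) for g in genes]
    if not genes:
        raise ValueError("empty gene list")
    if pvalues is not None:
        p = np.asarray(pvalues, dtype=float)
        if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
            raise ValueError("p-values must lie in (0, 1]")
        if len(p) != len(genes):
            raise ValueError("p-values not aligned with genes")
        mode = "full" if coefficients is not None else "ordered"
        coefs = (
            np.asarray(coefficients, dtype=float)
            if coefficients is not None
            else None
        )
    elif coefficients is not None:
        raise ValueError("coefficients without p-values are not supported")
    else:
        n = len(genes)
        # ordered input is flagged by the caller passing a list; without
        # p-values we cannot distinguish, so the caller chooses the mode via
        # prepare_ordered / prepare_unordered below
        mode = "unordered"
        p = np.full(n, SYNTH_PVALUE)
        coefs = None
    # collapse duplicates
    if len(set(genes)) != len(genes):
        df = pd.DataFrame({"gene": genes, "p": p})
        if coefs is not None:
            df["coef"] = coefs
        if collapse == "min_p":
            df = df.sort_values("p", kind="mergesort")
            df = df.drop_duplicates("gene", keep="first")
            df = df.sort_index()
        elif collapse == "first":
            df = df.drop_duplicates("gene", keep="first")
        else:
            raise ValueError(f"unknown collapse rule {collapse!r}")
        genes = list(df["gene"])
        p = df["p"].to_numpy()
        coefs = df["coef"].to_numpy() if coefs is not None else None
    if mode in ("ordered", "unordered") and pvalues is None:
        n = len(genes)
        p = np.full(n, SYNTH_PVALUE)
    return UserQuery(
        genes=genes, pvalues=p, coefficients=coefs, mode=mode
    )


def prepare_ordered(genes, uppercase: bool = False) -> UserQuery:
    """An ordered gene list without statistics: evenly spaced p-values.

    p_i = 0.049 i / n for rank i, so the least significant gene sits at
    exactly 0.049; the Pearson channel is disabled downstream.
    """
    q = prepare_user_input(genes, uppercase=uppercase)
    n = len(q.genes)
    return UserQuery(
        genes=q.genes,
        pvalues=SYNTH_PVALUE * np.arange(1, n + 1) / n,
        coefficients=None,
        mode="ordered",
    )


def prepare_unordered(genes, uppercase: bool = False) -> UserQuery:
    """An unordered gene set: every p-value 0.049, no correlations."""
    return prepare_user_input(genes, uppercase=uppercase)


def resolve_background(q: UserQuery, c: Compendium) -> frozenset:
    """The statistical background: user-supplied, else the compendium universe.

    Query genes missing from the background are appended with a warning so
    the ranked test's preconditions hold.
    """
    bg = q.background if q.background else c.universe
    if not bg:
        raise ValueError("no background: compendium universe is empty")
    missing = [g for g in q.genes if g not in bg]
    if missing:
        logger.warning(
            "%d query genes absent from the background; appending", len(missing)
        )
        bg = frozenset(bg) | frozenset(missing)
    return frozenset(bg)


def _rank_channel(df: pd.DataFrame) -> pd.DataFrame:
    """Dense 1-based ranks by (fdr, p), stable order."""
    df = df.sort_values(["fdr", "pvalue", "comparison"], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def _term_overlap_channel(
    user_terms, comp_terms_by_id, universe_size: int, alpha: float
) -> pd.DataFrame:
    """Hypergeometric overlap of significant term sets, BH across comparisons."""
    rows = []
    user_sig = {h.term_id for h in user_terms if h.fdr < alpha}
    for comp_id, terms in comp_terms_by_id.items():
        comp_sig = {tid for tid, q in terms if q < alpha}
        k = len(user_sig & comp_sig)
        if universe_size and user_sig and comp_sig:
            p, odds = hypergeom_overlap_test(
                k, len(comp_sig), len(user_sig), universe_size
            )
        else:
            p, odds = 1.0, np.nan
        rows.append(
            {
                "comparison": comp_id,
                "pvalue": p,
                "odds_ratio": odds,
                "n_overlap": k,
                "overlap_terms": sorted(user_sig & comp_sig),
            }
        )
    df = pd.DataFrame(
        rows, columns=["comparison", "pvalue", "odds_ratio", "n_overlap", "overlap_terms"]
    )
    df["fdr"] = bh_fdr(df["pvalue"]) if len(df) else []
    return _rank_channel(df)


def _deg_overlap_channel(
    q: UserQuery, c: Compendium, background, alpha: float
) -> pd.DataFrame:
    deg_db = compendium_to_gmt(c, "all")
    hits = enrich_list_against_db(q.ranked_genes(), deg_db, background, alpha)
    df = pd.DataFrame(
        [
            {
                "comparison": h.term_id,
                "pvalue": h.pvalue,
                "fdr": h.fdr,
                "best_rank_depth": h.best_rank_depth,
                "overlap_genes": h.overlap_genes,
            }
            for h in hits
        ],
        columns=["comparison", "pvalue", "fdr", "best_rank_depth", "overlap_genes"],
    )
    return _rank_channel(df)


def correlate_with_comparison(coefs: pd.Series, comp: ComparisonRecord):
    """Correlate user coefficients with a comparison's DEG log2 fold-changes.

    Computed on genes DE in the comparison and present in the user list;
    returns (spearman_rho, pearson_r, p_s, p_p, n), NaN when fewer than 3
    genes overlap or either vector is constant.
    """
    lfc = comp.log2fc_series()
    shared = [g for g in coefs.index if g in comp.deg_genes()]
    n = len(shared)
    out = [np.nan, np.nan, np.nan, np.nan, n]
    if n < 3:
        return tuple(out)
    x = coefs.loc[shared].to_numpy(dtype=float)
    y = lfc.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return tuple(out)
    rho, p_s = stats.spearmanr(x, y)
    r, p_p = stats.pearsonr(x, y)
    return float(rho), float(r), float(p_s), float(p_p), n


def _correlation_channel(
    q: UserQuery, c: Compendium, deg_overlap: pd.DataFrame, alpha: float
) -> pd.DataFrame:
    cols = [
        "comparison",
        "spearman_rho",
        "pearson_r",
        "pvalue",
        "pearson_p",
        "n_overlap",
    ]
    coefs = q.coefficient_series()
    if coefs is None:
        df = pd.DataFrame(columns=cols)
        df["fdr"] = []
        df["rank"] = []
        return df
    enriched = deg_overlap.loc[deg_overlap["fdr"] < alpha, "comparison"]
    rows = []
    for comp_id in enriched:
        comp = c[comp_id]
        rho, r, p_s, p_p, n = correlate_with_comparison(coefs, comp)
        rows.append(
            {
                "comparison": comp_id,
                "spearman_rho": rho,
                "pearson_r": r if q.mode == "full" else np.nan,
                "pvalue": p_s,
                "pearson_p": p_p if q.mode == "full" else np.nan,
                "n_overlap": n,
            }
        )
    df = pd.DataFrame(rows, columns=cols)
    ok = df["pvalue"].notna()
    df["fdr"] = np.nan
    if ok.any():
        df.loc[ok, "fdr"] = bh_fdr(df.loc[ok, "pvalue"])
    df = df.sort_values(
        ["fdr", "pvalue", "comparison"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def deet_enrich(
    q: UserQuery,
    c: Compendium,
    pathway_db: GeneSetDB | None = None,
    tf_db: GeneSetDB | None = None,
    alpha: float = 0.05,
) -> EnrichmentReport:
    """The primary query: four channels against every comparison."""
    if len(c) == 0:
        raise ValueError("compendium is empty")
    background = resolve_background(q, c)
    ranked = q.ranked_genes()
    user_pathways: list = []
    user_tfs: list = []
    pathway_overlap = pd.DataFrame(
        columns=["comparison", "pvalue", "odds_ratio", "n_overlap", "overlap_terms", "fdr", "rank"]
    )
    tf_overlap = pathway_overlap.copy()
    if pathway_db is not None:
        fdb = filter_gene_sets(pathway_db, *PATHWAY_SIZE_WINDOW, universe=background)
        user_pathways = enrich_list_against_db(ranked, fdb, background, alpha)
        pathway_overlap = _term_overlap_channel(
            user_pathways,
            {comp.id: comp.enriched_pathways for comp in c},
            len(fdb),
            alpha,
        )
    if tf_db is not None:
        fdb = filter_gene_sets(tf_db, *TF_SIZE_WINDOW, universe=background)
        user_tfs = enrich_list_against_db(ranked, fdb, background, alpha)
        tf_overlap = _term_overlap_channel(
            user_tfs,
            {comp.id: comp.enriched_tfs for comp in c},
            len(fdb),
            alpha,
        )
    deg_overlap = _deg_overlap_channel(q, c, background, alpha)
    correlations = _correlation_channel(q, c, deg_overlap, alpha)
    return EnrichmentReport(
        deg_overlap=deg_overlap,
        pathway_overlap=pathway_overlap,
        tf_overlap=tf_overlap,
        correlations=correlations,
        user_pathways=user_pathways,
        user_tfs=user_tfs,
        mode=q.mode,
    )


def enrich_genesonly(
    q: UserQuery, c: Compendium, alpha: float = 0.05, namespace: str = "symbol"
) -> EnrichmentReport:
    """Gene-centric query: DEG overlap + correlations, no term channels.

    With ``namespace="ensembl"`` no symbol-casing normalisation is applied,
    making the query usable for pseudogenes / non-coding IDs; a mixed
    namespace simply yields empty overlaps (warned).
    """
    if namespace not in ("symbol", "ensembl"):
        raise ValueError(f"unknown identifier namespace {namespace!r}")
    rep = deet_enrich(q, c, pathway_db=None, tf_db=None, alpha=alpha)
    if (rep.deg_overlap["best_rank_depth"] > 0).sum() == 0:
        logger.warning(
            "no query gene overlaps any comparison; check the identifier namespace"
        )
    return rep


def input_as_reference(
    user_genes, c: Compendium, alpha: float = 0.05
) -> pd.DataFrame:
    """Reverse query: each comparison's FDR-ranked DEG list vs the user set.

    The user list becomes a single-set database and every comparison's DEG
    list (ranked by ascending FDR) is the weighted query, so enrichment
    reflects the significance profile of the precomputed DEGs rather than
    plain overlap. BH across comparisons.
    """
    user_genes = list(dict.fromkeys(user_genes))
    if not user_genes:
        raise ValueError("empty user gene list")
    user_set = GeneSet(id="user", name="user", genes=frozenset(user_genes))
    background = frozenset(c.universe) | user_set.genes
    rows = []
    for comp in c:
        hit = ranked_hypergeometric(comp.ranked_degs(), user_set, background)
        rows.append(
            {
                "comparison": comp.id,
                "pvalue": hit.pvalue,
                "best_rank_depth": hit.best_rank_depth,
                "overlap_genes": hit.overlap_genes,
            }
        )
    df = pd.DataFrame(
        rows, columns=["comparison", "pvalue", "best_rank_depth", "overlap_genes"]
    )
    df["fdr"] = bh_fdr(df["pvalue"]) if len(df) else []
    return _rank_channel(df)


def report_tables(
    rep: EnrichmentReport,
    top_n: int = 15,
    scatter_comparison: str | None = None,
    compendium: Compendium | None = None,
    query: UserQuery | None = None,
):
    """Tidy top-N tables per channel plus an optional scatter table.

    Each channel table carries a ``neg_log10_fdr`` column for barplots; the
    scatter table pairs user coefficients with a chosen comparison's log2
    fold-changes and classifies genes as same-sign / opposite / one-only.
    """
    tables = {}
    for name in ("deg_overlap", "pathway_overlap", "tf_overlap", "correlations"):
        df = getattr(rep, name).head(top_n).copy()
        if "fdr" in df.columns and len(df):
            with np.errstate(divide="ignore"):
                df["neg_log10_fdr"] = -np.log10(df["fdr"].astype(float))
        else:
            df["neg_log10_fdr"] = pd.Series(dtype=float)
        tables[name] = df
    if scatter_comparison is not None:
        if compendium is None or query is None:
            raise ValueError("scatter table needs the compendium and the query")
        comp = compendium[scatter_comparison]
        coefs = query.coefficient_series()
        if coefs is None:
            raise ValueError("scatter table needs coefficients (full/ordered mode)")
        lfc = comp.log2fc_series()
        degs = comp.deg_genes()
        rows = []
        for g in set(coefs.index) | set(degs):
            u = coefs.get(g, np.nan)
            v = lfc.get(g, np.nan) if g in degs else np.nan
            if np.isnan(u) or np.isnan(v):
                cls = "one-only"
            elif u * v > 0:
                cls = "same-sign"
            else:
                cls = "opposite"
            rows.append(
                {"gene": g, "user_coefficient": u, "comparison_log2fc": v, "agreement": cls}
            )
        tables["scatter"] = (
            pd.DataFrame(rows).sort_values("gene").reset_index(drop=True)
        )
    return tables


def overlap_stats(study_degs, compendium_degs):
    """Overlap bookkeeping between an original study's DEGs and recomputed DEGs.

    Returns a dict with the tool-specific, study-specific and intersecting
    DEG counts plus ``genes_captured_pct`` — the intersecting count as a
    percentage of the study-specific count, the convention used when
    benchmarking recomputed DEG lists against their original studies.
    """
    s = frozenset(study_degs)
    d = frozenset(compendium_degs)
    inter = len(s & d)
    study_only = len(s - d)
    comp_only = len(d - s)
    captured = 100.0 * inter / study_only if study_only else np.nan
    return {
        "compendium_specific": comp_only,
        "study_specific": study_only,
        "intersecting": inter,
        "genes_captured_pct": captured,
    }
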