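"""Assembling a compendium from raw comparison results.

A candidate comparison enters the compendium only if it passes the
interpretability rules applied uniformly across sources:

* at least three biological replicates per condition;
* conditions are not generic identifiers (caller-provided flag — sample-ID
  groupings cannot be detected automatically);
* both groups come from the same tissue;
* no controlled-for categorical variable perfectly stratifies the groups
  (such a design is unidentifiable);
* neither condition is the literal ``NA`` / ``unknown`` level;
* time-series / dosage pairs must be reference-vs-adjacent steps — a pair
  skipping an existing intermediate level (Time-2 vs Time-4 with Time-3
  present) is out;
* in studies with more than three candidate comparisons, only
  treatment-vs-control pairs are kept (treatment-vs-treatment permutations
  would otherwise dominate);
* after DE, comparisons with fewer than 5 or more than 10000 DEGs are
  dropped.

Included comparisons are named ``STUDY: Tissue.condA vs condB`` with the
conditions in alphabetical order, annotated with ranked-hypergeometric
pathway (15–2000 genes) and TF-target (15–5000 genes) enrichment against
the comparison's detected genes, and given a summary card (top 15 up / down
DEGs, top 5 pathways / TFs, sample and DEG counts).
"""

from __future__ import annotations

import dataclasses
import logging

import pandas as pd

from .core import Compendium, ComparisonRecord, GeneSetDB, filter_gene_sets
from .diffexp import DEResult, deg_count_filter
from .enrichment import enrich_list_against_db

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryCard",
    "DesignSpec",
    "check_inclusion",
    "name_comparison",
    "annotate_comparison",
    "build_compendium",
    "PATHWAY_SIZE_WINDOW",
    "TF_SIZE_WINDOW",
]

PATHWAY_SIZE_WINDOW = (15, 2000)
TF_SIZE_WINDOW = (15, 5000)

_MISSING_LEVELS = {"na", "unknown", ""}


@dataclasses.dataclass
class SummaryCard:
    top_up: list
    top_down: list
    top_pathways: list
    top_tfs: list
    n_de_total: int
    n_de_up: int
    n_de_down: int
    n_samples_total: int
    n_samples_up: int
    n_samples_down: int
    description: str = ""

    def __post_init__(self):
        if len(self.top_up) > 15 or len(self.top_down) > 15:
            raise ValueError("top DEG lists are capped at 15")
        if len(self.top_pathways) > 5 or len(self.top_tfs) > 5:
            raise ValueError("top term lists are capped at 5")


@dataclasses.dataclass
class DesignSpec:
    """Description of one candidate comparison for the inclusion rules."""

    study_id: str
    tissue1: str
    tissue2: str
    cond1: str
    cond2: str
    n1: int
    n2: int
    source: str = "synthetic"
    category: str = ""
    description: str = ""
    controlled_categoricals: dict = dataclasses.field(default_factory=dict)
    #: for time-series / dosage studies: the ordered level sequence
    time_levels: tuple | None = None
    generic_conditions: bool = False
    #: total candidate comparisons in the study, and whether this pair
    #: involves the untreated control
    study_n_comparisons: int = 1
    is_treatment_vs_treatment: bool = False


def check_inclusion(spec: DesignSpec):
    """Apply the uniform exclusion rules; returns (include, reasons)."""
    reasons = []
    if min(spec.n1, spec.n2) < 3:
        reasons.append("replicates")
    if spec.generic_conditions:
        reasons.append("generic-conditions")
    if spec.tissue1 != spec.tissue2:
        reasons.append("cross-tissue")
    for var, values in spec.controlled_categoricals.items():
        g1 = {str(v) for v in values.get(spec.cond1, [])}
        g2 = {str(v) for v in values.get(spec.cond2, [])}
        if g1 and g2 and not (g1 & g2):
            reasons.append(f"stratification:{var}")
    if {spec.cond1.lower(), spec.cond2.lower()} & _MISSING_LEVELS:
        reasons.append("missing-condition-label")
    if spec.time_levels is not None:
        levels = list(spec.time_levels)
        try:
            i, j = levels.index(spec.cond1), levels.index(spec.cond2)
        except ValueError:
            i = j = None
        if i is not None:
            lo, hi = min(i, j), max(i, j)
            # keep reference-anchored pairs and adjacent steps; a pair that
            # skips an existing intermediate level is non-linear
            if lo != 0 and hi - lo > 1:
                reasons.append("nonlinear-timepoint")
    if spec.study_n_comparisons > 3 and spec.is_treatment_vs_treatment:
        reasons.append("treatment-vs-treatment")
    return (not reasons), reasons


def name_comparison(study_id: str, tissue: str, cond1: str, cond2: str) -> str:
    """``STUDY: Tissue.condA vs condB`` with conditions alphabetical."""
    if not all((study_id, tissue, cond1, cond2)):
        raise ValueError("empty naming field")
    a, b = sorted([cond1, cond2])
    return f"{study_id}: {tissue}.{a} vs {b}"


def annotate_comparison(
    r: ComparisonRecord,
    pathway_db: GeneSetDB | None,
    tf_db: GeneSetDB | None,
) -> ComparisonRecord:
    """Attach ranked-hypergeometric pathway / TF enrichment to a comparison.

    The query is the comparison's DEG list ranked by ascending FDR (both
    directions together) and the background its detected genes; databases
    are size-filtered within that background. All terms are stored with
    their FDR regardless of significance.
    """
    ranked = r.ranked_degs()
    bg = r.detected_genes
    for db, window, attr in (
        (pathway_db, PATHWAY_SIZE_WINDOW, "enriched_pathways"),
        (tf_db, TF_SIZE_WINDOW, "enriched_tfs"),
    ):
        if db is None:
            continue
        filtered = filter_gene_sets(db, *window, universe=bg)
        hits = enrich_list_against_db(ranked, filtered, bg) if ranked else []
        setattr(r, attr, [(h.term_id, h.fdr) for h in hits])
    return r


def _summary_card(r: ComparisonRecord, spec: DesignSpec) -> SummaryCard:
    t = r.deg_table[r.deg_table["is_de"]].copy()
    t["_absfc"] = -t["log2fc"].abs()
    t = t.sort_values(["fdr", "_absfc", "gene"], kind="mergesort")
    up = list(t.loc[t["log2fc"] > 0, "gene"].head(15))
    down = list(t.loc[t["log2fc"] < 0, "gene"].head(15))
    sig = lambda terms: [tid for tid, q in terms if q < 0.05][:5]
    a, b = sorted([spec.cond1, spec.cond2])
    n_up = spec.n2 if a == spec.cond1 else spec.n1
    n_down = spec.n1 if a == spec.cond1 else spec.n2
    return SummaryCard(
        top_up=up,
        top_down=down,
        top_pathways=sig(r.enriched_pathways),
        top_tfs=sig(r.enriched_tfs),
        n_de_total=int(r.deg_table["is_de"].sum()),
        n_de_up=int((t["log2fc"] > 0).sum()),
        n_de_down=int((t["log2fc"] < 0).sum()),
        n_samples_total=spec.n1 + spec.n2,
        n_samples_up=n_up,
        n_samples_down=n_down,
        description=spec.description,
    )


def build_compendium(
    results,
    pathway_db: GeneSetDB | None = None,
    tf_db: GeneSetDB | None = None,
):
    """Assemble a :class:`Compendium` from (DEResult, DesignSpec) pairs.

    Returns ``(compendium, build_report)`` where the report is a tidy table
    with one row per candidate and the machine-readable exclusion reasons.
    Every exclusion is attributable: kept + excluded = input.
    """
    records = []
    report_rows = []
    seen_names = {}
    for de, spec in results:
        name = name_comparison(spec.study_id, spec.tissue1, spec.cond1, spec.cond2)
        include, reasons = check_inclusion(spec)
        if include:
            keep, why = deg_count_filter(de)
            if not keep:
                include, reasons = False, [why.split(" ")[0]]
        report_rows.append(
            {
                "name": name,
                "included": include,
                "reasons": ";".join(reasons),
            }
        )
        if not include:
            continue
        if name in seen_names:
            seen_names[name] += 1
            logger.warning("duplicate comparison name %r; suffixing", name)
            name = f"{name} ({seen_names[name]})"
        else:
            seen_names[name] = 1
        tab = de.deg_table
        detected = frozenset(tab.loc[tab["pvalue"].notna(), "gene"])
        rec = ComparisonRecord(
            id=name,
            name=name,
            source=spec.source,
            category=spec.category,
            deg_table=tab,
            detected_genes=detected,
            n_samples_total=spec.n1 + spec.n2,
        )
        annotate_comparison(rec, pathway_db, tf_db)
        rec.summary_card = _summary_card(rec, spec)
        rec.n_samples_up = rec.summary_card.n_samples_up
        rec.n_samples_down = rec.summary_card.n_samples_down
        records.append(rec)
    report = pd.DataFrame(
        report_rows, columns=["name", "included", "reasons"]
    )
    return Compendium(comparisons=records), report
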