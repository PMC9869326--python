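"""Core domain types and shared I/O.

The central objects are:

* :class:`GeneSet` / :class:`GeneSetDB` — gene-set databases in the Broad
  gene-matrix-transpose (GMT) dialect, used both for pathway / TF-target
  annotation and for exporting the compendium's DEG lists.
* :class:`ComparisonRecord` — one pairwise differential-expression
  comparison: a per-gene table of log2 fold-changes and (adjusted) p-values,
  the detected-gene background, and its enrichment annotation.
* :class:`Compendium` — the collection of comparisons plus the union gene
  universe, which acts as the default statistical background for queries.

Multiple-testing correction is Benjamini–Hochberg throughout (``bh_fdr``).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "GeneSetDB",
    "ComparisonRecord",
    "Compendium",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "filter_gene_sets",
    "bh_fdr",
    "compendium_to_gmt",
    "make_deg_table",
    "validate_deg_table",
]

#: required columns of a DEG table, in canonical order
DEG_COLUMNS = ("gene", "log2fc", "pvalue", "fdr", "is_de")


class GmtParseError(ValueError):
    """Raised for malformed GMT lines; carries the 1-based line number."""


@dataclasses.dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (e.g. one pathway or TF-target set)."""

    id: str
    name: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclasses.dataclass
class GeneSetDB:
    """An ordered collection of :class:`GeneSet` with unique ids."""

    sets: list
    source_label: str = ""

    def __post_init__(self):
        ids = [s.id for s in self.sets]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene-set ids: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.id == set_id:
                return s
        raise KeyError(set_id)

    @property
    def ids(self) -> list:
        return [s.id for s in self.sets]


def make_deg_table(
    genes: Sequence[str],
    log2fc: Sequence[float],
    pvalue: Sequence[float],
    fdr: Sequence[float] | None = None,
    fdr_cut: float = 0.05,
    abs_fc_cut: float = 1.0,
) -> pd.DataFrame:
    """Assemble a DEG table; FDR defaults to BH over ``pvalue``.

    ``is_de`` is set from the cutoffs (``fdr < fdr_cut`` and
    ``|log2fc| >= log2(abs_fc_cut)``); genes with missing p-values (failed
    fits) are never called DE and are excluded from the BH correction.
    """
    p = np.asarray(pvalue, dtype=float)
    lfc = np.asarray(log2fc, dtype=float)
    if fdr is None:
        q = np.full_like(p, np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            q[ok] = bh_fdr(p[ok])
    else:
        q = np.asarray(fdr, dtype=float)
    tab = pd.DataFrame(
        {"gene": list(genes), "log2fc": lfc, "pvalue": p, "fdr": q}
    )
    tab["is_de"] = (tab["fdr"] < fdr_cut) & (
        tab["log2fc"].abs() >= math.log2(abs_fc_cut)
    )
    tab["is_de"] = tab["is_de"].fillna(False).astype(bool)
    return tab


def validate_deg_table(tab: pd.DataFrame) -> pd.DataFrame:
    """Check column presence and value ranges of a DEG table."""
    missing = [c for c in DEG_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"DEG table missing columns: {missing}")
    for col in ("pvalue", "fdr"):
        vals = tab[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    if tab["gene"].duplicated().any():
        raise ValueError("duplicate gene identifiers in DEG table")
    return tab


@dataclasses.dataclass
class ComparisonRecord:
    """One pairwise DE comparison with its annotation.

    ``deg_table`` holds every tested gene; ``detected_genes`` is the
    statistical background (all genes detected in the comparison, DE or
    not). Enrichment annotations store *all* terms with their FDR, the
    significance mark being FDR < 0.05 by convention downstream.
    """

    id: str
    name: str
    source: str  # SRA | TCGA | GTEx | SRA-manual | synthetic
    category: str
    deg_table: pd.DataFrame
    detected_genes: frozenset
    n_samples_total: int = 0
    n_samples_up: int = 0
    n_samples_down: int = 0
    enriched_pathways: list = dataclasses.field(default_factory=list)
    enriched_tfs: list = dataclasses.field(default_factory=list)
    summary_card: "object | None" = None

    def __post_init__(self):
        validate_deg_table(self.deg_table)
        degs = self.deg_genes()
        if not degs <= self.detected_genes:
            raise ValueError("DEG set is not a subset of detected genes")

    def deg_genes(self, direction: str = "all") -> frozenset:
        """DEG identifiers, optionally restricted by fold-change sign."""
        t = self.deg_table
        mask = t["is_de"]
        if direction == "up":
            mask = mask & (t["log2fc"] > 0)
        elif direction == "down":
            mask = mask & (t["log2fc"] < 0)
        elif direction != "all":
            raise ValueError(f"unknown direction {direction!r}")
        return frozenset(t.loc[mask, "gene"])

    def ranked_degs(self) -> list:
        """DEGs ranked by ascending FDR, ties by descending |log2fc| then id."""
        t = self.deg_table[self.deg_table["is_de"]].copy()
        t["_absfc"] = -t["log2fc"].abs()
        t = t.sort_values(["fdr", "_absfc", "gene"], kind="mergesort")
        return list(t["gene"])

    def fdr_series(self) -> pd.Series:
        return self.deg_table.set_index("gene")["fdr"]

    def log2fc_series(self) -> pd.Series:
        return self.deg_table.set_index("gene")["log2fc"]


@dataclasses.dataclass
class Compendium:
    """A collection of comparisons plus the union gene universe."""

    comparisons: list

    def __post_init__(self):
        ids = [c.id for c in self.comparisons]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate comparison ids in compendium")

    def __len__(self) -> int:
        return len(self.comparisons)

    def __iter__(self):
        return iter(self.comparisons)

    def __getitem__(self, comp_id: str) -> ComparisonRecord:
        for c in self.comparisons:
            if c.id == comp_id:
                return c
        raise KeyError(comp_id)

    @property
    def universe(self) -> frozenset:
        """Genes detected in at least one comparison."""
        out = set()
        for c in self.comparisons:
            out |= c.detected_genes
        return frozenset(out)


# ---------------------------------------------------------------------------
# GMT I/O (Broad gene-matrix-transpose dialect: id, description, genes...)
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetDB:
    """Parse a GMT file: one gene set per tab-separated line.

    Duplicate genes within a line are collapsed, empty gene fields dropped.
    Lines with fewer than three fields raise :class:`GmtParseError` naming
    the line number.
    """
    path = Path(path)
    sets = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise GmtParseError(
                    f"{path.name}:{lineno}: gene set {fields[0]!r} has no genes"
                )
            sets.append(GeneSet(id=fields[0], name=fields[1], genes=genes))
    return GeneSetDB(sets=sets, source_label=str(path))


def write_gmt(db: GeneSetDB, path) -> None:
    """Write a GeneSetDB as GMT; round-trips id/name/gene content."""
    if len(db) == 0:
        raise ValueError("refusing to write an empty gene-set database")
    path = Path(path)
    with path.open("w") as fh:
        for s in db:
            for field in (s.id, s.name, *s.genes):
                if "\t" in field or "\n" in field:
                    raise ValueError(
                        f"field {field!r} in set {s.id!r} contains a "
                        "tab/newline and cannot be written as GMT"
                    )
            genes = sorted(s.genes)
            fh.write("\t".join([s.id, s.name, *genes]) + "\n")


def filter_gene_sets(
    db: GeneSetDB,
    min_size: int,
    max_size: int,
    universe: Iterable | None = None,
) -> GeneSetDB:
    """Size-window filter, optionally after intersecting with a background.

    Pathway databases conventionally use the 15–2000 window and TF-target
    databases 15–5000; the window is applied to set sizes *within* the
    background when one is given, so term genes never detected do not count.
    """
    if not (0 < min_size <= max_size):
        raise ValueError("need 0 < min_size <= max_size")
    uni = frozenset(universe) if universe is not None else None
    kept = []
    for s in db:
        genes = s.genes if uni is None else s.genes & uni
        if min_size <= len(genes) <= max_size:
            kept.append(GeneSet(id=s.id, name=s.name, genes=frozenset(genes)))
    return GeneSetDB(sets=kept, source_label=db.source_label)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1] with no NaN")
    return multipletests(p, method="fdr_bh")[1]


def compendium_to_gmt(c: Compendium, direction: str = "all") -> GeneSetDB:
    """Export each comparison's DEG set as a gene set.

    ``direction`` picks all DEGs or only the up-/down-regulated side;
    comparisons with no DEGs in the chosen direction are omitted.
    """
    if len(c) == 0:
        raise ValueError("compendium is empty")
    sets = []
    for comp in c:
        genes = comp.deg_genes(direction)
        if genes:
            sets.append(GeneSet(id=comp.id, name=comp.name, genes=genes))
    return GeneSetDB(sets=sets, source_label=f"compendium-{direction}")
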