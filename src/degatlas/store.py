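"""TSV-first on-disk layout for a compendium.

One concept per file, all plain text, so a compendium directory is
diff-able and regenerable byte-identically from (inputs, config, seed):

* ``manifest.tsv`` — one row per comparison (id, name, source, category,
  sample counts, file pointer);
* ``deg/<k>.tsv`` — the per-gene table (gene, log2fc, pvalue, fdr, is_de,
  detected) for comparison k;
* ``pathways.tsv`` / ``tfs.tsv`` — long tables of (comparison, term, fdr);
* ``degs.gmt`` — every comparison's DEG list in GMT for use with external
  enrichment tools.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import Compendium, ComparisonRecord, compendium_to_gmt, write_gmt

__all__ = ["save_compendium", "load_compendium"]


def save_compendium(c: Compendium, out_dir) -> None:
    out = Path(out_dir)
    (out / "deg").mkdir(parents=True, exist_ok=True)
    manifest = []
    path_rows, tf_rows = [], []
    for k, comp in enumerate(c):
        tab = comp.deg_table.copy()
        tab["detected"] = tab["gene"].isin(comp.detected_genes)
        # 17 significant digits: doubles round-trip exactly through text
        tab.to_csv(
            out / "deg" / f"{k}.tsv", sep="\t", index=False,
            float_format="%.17g",
        )
        manifest.append(
            {
                "id": comp.id,
                "name": comp.name,
                "source": comp.source,
                "category": comp.category,
                "n_samples_total": comp.n_samples_total,
                "n_samples_up": comp.n_samples_up,
                "n_samples_down": comp.n_samples_down,
                "deg_file": f"deg/{k}.tsv",
            }
        )
        path_rows += [
            {"comparison": comp.id, "term": t, "fdr": q}
            for t, q in comp.enriched_pathways
        ]
        tf_rows += [
            {"comparison": comp.id, "term": t, "fdr": q}
            for t, q in comp.enriched_tfs
        ]
    manifest_cols = [
        "id", "name", "source", "category", "n_samples_total",
        "n_samples_up", "n_samples_down", "deg_file",
    ]
    pd.DataFrame(manifest, columns=manifest_cols).to_csv(
        out / "manifest.tsv", sep="\t", index=False
    )
    cols = ["comparison", "term", "fdr"]
    pd.DataFrame(path_rows, columns=cols).to_csv(
        out / "pathways.tsv", sep="\t", index=False, float_format="%.17g"
    )
    pd.DataFrame(tf_rows, columns=cols).to_csv(
        out / "tfs.tsv", sep="\t", index=False, float_format="%.17g"
    )
    if any(comp.deg_genes() for comp in c):
        write_gmt(compendium_to_gmt(c, "all"), out / "degs.gmt")


def load_compendium(in_dir) -> Compendium:
    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.tsv", sep="\t")
    ann = {
        name: pd.read_csv(src / f"{name}.tsv", sep="\t")
        for name in ("pathways", "tfs")
        if (src / f"{name}.tsv").exists()
    }
    records = []
    for _, row in manifest.iterrows():
        tab = pd.read_csv(src / row["deg_file"], sep="\t")
        detected = frozenset(tab.loc[tab.pop("detected"), "gene"].astype(str))
        tab["gene"] = tab["gene"].astype(str)
        terms = {}
        for name in ("pathways", "tfs"):
            if name in ann and len(ann[name]):
                sub = ann[name][ann[name]["comparison"] == row["id"]]
                terms[name] = list(zip(sub["term"], sub["fdr"]))
            else:
                terms[name] = []
        records.append(
            ComparisonRecord(
                id=str(row["id"]),
                name=str(row["name"]),
                source=str(row["source"]),
                category="" if pd.isna(row["category"]) else str(row["category"]),
                deg_table=tab,
                detected_genes=detected,
                n_samples_total=int(row["n_samples_total"]),
                n_samples_up=int(row["n_samples_up"]),
                n_samples_down=int(row["n_samples_down"]),
                enriched_pathways=terms["pathways"],
                enriched_tfs=terms["tfs"],
            )
        )
    return Compendium(comparisons=records)
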