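"""Synthetic data with planted truth.

Everything the pipeline consumes can be generated here deterministically
from a seed: count matrices with known differential genes (NB counts with
log-normal baselines and planted log2 fold-changes), whole compendia with a
planted block structure (shared DEG cores within blocks, private DEGs
elsewhere), and gene-set databases optionally containing a planted set.
Each generator returns a :class:`SimTruth` recording what was planted so
tests can score recovery.

The default parameter values describe a small but realistically shaped
experiment: 2000 genes, 6 samples per group, 10% DE genes with half-normal
effect sizes around one log2 unit, and NB dispersion 0.1 — a mid-range
gene-wise dispersion for bulk RNA-seq.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core import (
    Compendium,
    ComparisonRecord,
    GeneSet,
    GeneSetDB,
    make_deg_table,
)
from .diffexp import CountsExperiment

__all__ = [
    "SimTruth",
    "simulate_counts",
    "simulate_compendium",
    "simulate_genesets",
]


@dataclasses.dataclass
class SimTruth:
    de_genes: frozenset = frozenset()
    planted_log2fc: "pd.Series | None" = None
    batch_labels: "np.ndarray | None" = None
    planted_clusters: "pd.Series | None" = None
    planted_match: "str | None" = None


def _gene_names(n: int) -> list:
    return [f"G{i:05d}" for i in range(n)]


def simulate_counts(
    n_genes: int = 2000,
    n_per_group: int = 6,
    de_fraction: float = 0.1,
    lfc_scale: float = 1.0,
    dispersion: float = 0.1,
    batch_effect: float = 0.0,
    batch_confounded: bool = False,
    seed: int = 0,
):
    """NB counts for a two-group comparison with planted DE genes.

    Baseline means are log-normal; a random ``de_fraction`` of genes gets a
    Normal(0, lfc_scale) log2 fold-change in group "b" relative to group
    "a". An optional batch covers half the samples (balanced across groups,
    or confounded with the condition when ``batch_confounded``) and shifts
    a third of the genes by ``batch_effect`` log2 units. Returns
    ``(CountsExperiment, SimTruth)``, bit-reproducible per seed.
    """
    if not (0 <= de_fraction <= 1):
        raise ValueError("de_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    n = 2 * n_per_group
    base = rng.lognormal(mean=np.log(100.0), sigma=1.2, size=n_genes)
    cond = np.array(["a"] * n_per_group + ["b"] * n_per_group)
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    lfc = np.zeros(n_genes)
    if n_de:
        effects = rng.normal(0.0, lfc_scale, size=n_de)
        # keep planted effects away from zero so truth is well defined
        effects = np.sign(effects) * np.maximum(np.abs(effects), 0.25)
        lfc[de_idx] = effects
    if batch_confounded:
        batch = (cond == "b").astype(int)
    else:
        half = np.arange(n_per_group) % 2  # balanced within each group
        batch = np.concatenate([half, half])
    batch_lfc = np.zeros(n_genes)
    if batch_effect:
        hit = rng.choice(n_genes, size=n_genes // 3, replace=False)
        batch_lfc[hit] = rng.normal(0.0, batch_effect, size=len(hit))
    log2mu = (
        np.log2(base)[:, None]
        + lfc[:, None] * (cond == "b")[None, :]
        + batch_lfc[:, None] * batch[None, :]
    )
    mu = 2.0**log2mu
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam)
    exp = CountsExperiment(
        counts=pd.DataFrame(
            counts, index=genes, columns=[f"s{i}" for i in range(n)]
        ),
        sample_meta=pd.DataFrame(
            {"condition": cond, "batch": batch.astype(str)},
            index=[f"s{i}" for i in range(n)],
        ),
        condition="condition",
    )
    truth = SimTruth(
        de_genes=frozenset(genes[i] for i in de_idx),
        planted_log2fc=pd.Series(lfc, index=genes),
        batch_labels=batch,
    )
    return exp, truth


def _fixture_fdrs(rng, n, is_de):
    """FDR values shaped like thresholded DE output.

    Non-DE genes draw Uniform(0.05, 1]; DE genes draw Beta(1, 50)
    truncated below 0.05 so the 0.05 threshold separates them exactly.
    """
    fdr = rng.uniform(0.05, 1.0, size=n)
    n_de = int(is_de.sum())
    if n_de:
        draws = rng.beta(1.0, 50.0, size=4 * n_de)
        draws = draws[draws < 0.05]
        while len(draws) < n_de:
            extra = rng.beta(1.0, 50.0, size=4 * n_de)
            draws = np.concatenate([draws, extra[extra < 0.05]])
        fdr[is_de] = draws[:n_de]
    return np.clip(fdr, 1e-12, 1.0)


def simulate_compendium(
    n_comparisons: int = 12,
    n_blocks: int = 2,
    within_block_shared_fraction: float = 0.8,
    n_genes: int = 1500,
    n_degs: int = 120,
    detect_fraction: float = 0.9,
    query_size: int = 40,
    seed: int = 0,
):
    """A compendium with planted block structure and a planted query match.

    Comparisons are assigned to blocks round-robin; each block owns a core
    DEG set covering ``within_block_shared_fraction`` of every member's
    DEGs, the rest being private. Fold-changes of shared DEGs are
    correlated within a block (a common direction/magnitude plus noise).
    The first comparison is the ``planted_match``: its DEG list contains a
    designated ``query_size``-gene query (the truth's ``de_genes``) at its
    top FDR ranks. Returns ``(Compendium, SimTruth)``.
    """
    if n_blocks > n_comparisons:
        raise ValueError("n_blocks must not exceed n_comparisons")
    rng = np.random.default_rng(seed)
    genes = np.array(_gene_names(n_genes))
    n_core = int(round(within_block_shared_fraction * n_degs))
    block_core = {}
    block_core_lfc = {}
    for b in range(n_blocks):
        core = rng.choice(n_genes, size=n_core, replace=False)
        block_core[b] = core
        block_core_lfc[b] = rng.normal(0.0, 2.0, size=n_core)
    records = []
    labels = {}
    for i in range(n_comparisons):
        b = i % n_blocks
        core = block_core[b]
        others = np.setdiff1d(np.arange(n_genes), core)
        private = rng.choice(others, size=n_degs - n_core, replace=False)
        de_idx = np.concatenate([core, private])
        detected = np.zeros(n_genes, dtype=bool)
        detected[de_idx] = True
        extra = np.flatnonzero(~detected)
        n_extra = max(0, int(round(detect_fraction * n_genes)) - len(de_idx))
        detected[rng.choice(extra, size=min(n_extra, len(extra)), replace=False)] = True
        det_genes = genes[detected]
        is_de = np.isin(det_genes, genes[de_idx])
        lfc = rng.normal(0.0, 0.5, size=len(det_genes))
        # block-correlated fold-changes on the shared core
        core_pos = {g: k for k, g in enumerate(genes[core])}
        for k, g in enumerate(det_genes):
            if g in core_pos:
                lfc[k] = block_core_lfc[b][core_pos[g]] + rng.normal(0.0, 0.3)
            elif is_de[k]:
                lfc[k] = rng.normal(0.0, 2.0)
                if abs(lfc[k]) < 0.5:
                    lfc[k] = 0.5 * np.sign(lfc[k] or 1.0)
        fdr = _fixture_fdrs(rng, len(det_genes), is_de)
        pvals = np.clip(fdr * rng.uniform(0.3, 1.0, size=len(fdr)), 1e-15, 1.0)
        tab = make_deg_table(det_genes, lfc, pvals, fdr=fdr)
        name = f"SIM{seed:03d}: tissue{b}.ctrl vs cond{i:02d}"
        rec = ComparisonRecord(
            id=name,
            name=name,
            source="synthetic",
            category=f"block{b}",
            deg_table=tab,
            detected_genes=frozenset(det_genes),
            n_samples_total=12,
        )
        records.append(rec)
        labels[name] = b
    comp = Compendium(comparisons=records)
    # planted query: top-ranked DEGs of the first comparison
    first = records[0]
    query = first.ranked_degs()[:query_size]
    truth = SimTruth(
        de_genes=frozenset(query),
        planted_clusters=pd.Series(labels),
        planted_match=first.id,
    )
    return comp, truth


def simulate_genesets(
    n_sets: int = 50,
    size_range=(15, 100),
    universe=None,
    planted_in=None,
    seed: int = 0,
) -> GeneSetDB:
    """Random gene sets over a universe, optionally with a planted set."""
    rng = np.random.default_rng(seed)
    if universe is None:
        universe = _gene_names(2000)
    universe = list(universe)
    lo, hi = size_range
    if hi > len(universe):
        raise ValueError("size_range exceeds universe size")
    sets = []
    if planted_in is not None:
        sets.append(
            GeneSet(id="PLANTED", name="planted set", genes=frozenset(planted_in))
        )
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets.append(
            GeneSet(
                id=f"SET{i:04d}",
                name=f"random set {i}",
                genes=frozenset(universe[j] for j in members),
            )
        )
    return GeneSetDB(sets=sets, source_label=f"simulated(seed={seed})")
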