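import numpy as np
import pandas as pd
import pytest
from scipy import stats

from degatlas.core import Compendium
from degatlas.enrichment import ranked_hypergeometric
from degatlas.query import (
    correlate_with_comparison,
    deet_enrich,
    enrich_genesonly,
    input_as_reference,
    overlap_stats,
    prepare_ordered,
    prepare_unordered,
    prepare_user_input,
    report_tables,
    resolve_background,
)
from degatlas.simulate import simulate_genesets


class TestPrepareUserInput:
    def test_unordered_sets_all_pvalues_to_0049(self):
        q = prepare_unordered(["a", "b", "c", "d", "e"])
        np.testing.assert_allclose(q.pvalues, 0.049)
        assert q.mode == "unordered" and q.coefficient_series() is None

    def test_ordered_even_spacing_with_0049_ceiling(self):
        q = prepare_ordered(["a", "b", "c", "d", "e"])
        np.testing.assert_allclose(
            q.pvalues, [0.0098, 0.0196, 0.0294, 0.0392, 0.049]
        )
        assert q.pvalues.max() == pytest.approx(0.049)
        assert q.mode == "ordered"

    def test_full_input_passes_through(self):
        q = prepare_user_input(["a", "b"], [0.01, 0.2], [1.5, -0.3])
        assert q.mode == "full"
        np.testing.assert_allclose(q.pvalues, [0.01, 0.2])
        np.testing.assert_allclose(q.coefficients, [1.5, -0.3])

    def test_duplicate_collapse_min_p_vs_first(self):
        genes = ["a", "b", "a"]
        p = [0.5, 0.2, 0.01]
        coefs = [1.0, 2.0, 3.0]
        q_min = prepare_user_input(genes, p, coefs, collapse="min_p")
        assert dict(zip(q_min.genes, q_min.pvalues))["a"] == 0.01
        q_first = prepare_user_input(genes, p, coefs, collapse="first")
        assert dict(zip(q_first.genes, q_first.pvalues))["a"] == 0.5

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            prepare_user_input(["a"], [0.0])
        with pytest.raises(ValueError):
            prepare_user_input(["a"], [1.5])

    def test_uppercase_flag(self):
        q = prepare_unordered(["Tp53", "brca1"], uppercase=True)
        assert q.genes == ["TP53", "BRCA1"]


class TestResolveBackground:
    def test_defaults_to_compendium_universe(self, small_compendium):
        comp, _ = small_compendium
        q = prepare_unordered(sorted(comp.universe)[:10])
        assert resolve_background(q, comp) == comp.universe

    def test_missing_query_genes_appended(self, small_compendium):
        comp, _ = small_compendium
        q = prepare_unordered(["NOT_A_GENE"])
        bg = resolve_background(q, comp)
        assert "NOT_A_GENE" in bg

    def test_user_background_respected(self, small_compendium):
        comp, _ = small_compendium
        q = prepare_unordered(["a"])
        q.background = frozenset({"a", "b"})
        assert resolve_background(q, comp) == {"a", "b"}

    def test_empty_universe_errors(self):
        q = prepare_unordered(["a"])
        with pytest.raises(ValueError):
            resolve_background(q, Compendium(comparisons=[]))


class TestDeetEnrich:
    def test_planted_match_is_rank_one(self, small_compendium):
        comp, truth = small_compendium
        q = prepare_ordered(sorted(truth.de_genes))
        rep = deet_enrich(q, comp)
        top = rep.deg_overlap.iloc[0]
        assert top["comparison"] == truth.planted_match
        assert top["rank"] == 1 and top["fdr"] < 0.05

    def test_self_query_recovers_own_comparison(self, small_compendium):
        """A comparison's own DEG table queried back ranks itself first."""
        comp, _ = small_compendium
        rec = comp.comparisons[3]
        tab = rec.deg_table[rec.deg_table.is_de]
        q = prepare_user_input(
            list(tab.gene), list(np.clip(tab.pvalue, 1e-12, 1)), list(tab.log2fc)
        )
        rep = deet_enrich(q, comp)
        assert rep.deg_overlap.iloc[0]["comparison"] == rec.id
        corr = rep.correlations.set_index("comparison")
        assert corr.loc[rec.id, "pearson_r"] == pytest.approx(1.0)

    def test_disjoint_query_has_no_hits(self, small_compendium):
        comp, _ = small_compendium
        q = prepare_unordered([f"ALIEN{i}" for i in range(20)])
        rep = deet_enrich(q, comp)
        assert (rep.deg_overlap["fdr"] < 0.05).sum() == 0
        assert len(rep.correlations) == 0

    def test_unordered_mode_disables_correlations_but_not_deg_channel(
        self, small_compendium
    ):
        comp, truth = small_compendium
        genes = sorted(truth.de_genes)
        rep_u = deet_enrich(prepare_unordered(genes), comp)
        rep_o = deet_enrich(prepare_ordered(genes), comp)
        assert len(rep_u.correlations) == 0
        assert len(rep_o.correlations) > 0
        assert rep_o.correlations["pearson_r"].isna().all()
        # the DEG-overlap channel must not depend on the correlation mode;
        # both modes rank genes identically here (same input order)
        pd.testing.assert_frame_equal(
            rep_u.deg_overlap[["comparison", "pvalue"]],
            rep_o.deg_overlap[["comparison", "pvalue"]],
        )

    def test_term_channels_populated_with_db(self):
        # fresh compendium: annotation mutates the records
        from degatlas.simulate import simulate_compendium

        comp, truth = simulate_compendium(
            n_comparisons=12, n_blocks=2, n_genes=1500, seed=11
        )
        db = simulate_genesets(
            n_sets=25,
            size_range=(15, 80),
            universe=sorted(comp.universe),
            planted_in=sorted(truth.de_genes),
            seed=4,
        )
        # annotate the compendium with the same db, then query
        from degatlas.compendium import annotate_comparison

        for rec in comp:
            annotate_comparison(rec, db, None)
        q = prepare_ordered(sorted(truth.de_genes))
        rep = deet_enrich(q, comp, pathway_db=db)
        assert len(rep.user_pathways) > 0
        assert rep.user_pathways[0].term_id == "PLANTED"
        assert len(rep.pathway_overlap) == len(comp)
        # comparisons sharing the planted signal (block 0) outrank the rest
        top = rep.pathway_overlap.iloc[0]
        assert top["n_overlap"] >= 1
        assert "tissue0" in top["comparison"]

    def test_ranks_are_dense_permutations(self, small_compendium):
        comp, truth = small_compendium
        rep = deet_enrich(prepare_ordered(sorted(truth.de_genes)), comp)
        ranks = sorted(rep.deg_overlap["rank"])
        assert ranks == list(range(1, len(rep.deg_overlap) + 1))


class TestCorrelateWithComparison:
    def test_identical_vectors(self, small_compendium):
        comp, _ = small_compendium
        rec = comp.comparisons[0]
        degs = sorted(rec.deg_genes())[:10]
        coefs = rec.log2fc_series().loc[degs]
        rho, r, p_s, p_p, n = correlate_with_comparison(coefs, rec)
        assert rho == pytest.approx(1.0) and r == pytest.approx(1.0)
        assert n == 10

    def test_small_overlap_is_missing(self, small_compendium):
        comp, _ = small_compendium
        rec = comp.comparisons[0]
        degs = sorted(rec.deg_genes())[:2]
        coefs = pd.Series([1.0, 2.0], index=degs)
        rho, r, *_ , n = correlate_with_comparison(coefs, rec)
        assert np.isnan(rho) and np.isnan(r) and n == 2

    def test_planted_correlation_recovered(self, small_compendium):
        comp, _ = small_compendium
        rec = comp.comparisons[1]
        degs = sorted(rec.deg_genes())
        rng = np.random.default_rng(9)
        y = rec.log2fc_series().loc[degs].to_numpy()
        # bivariate-normal-style noise targeting r ~ 0.8
        x = 0.8 * (y / y.std()) + np.sqrt(1 - 0.64) * rng.normal(size=len(y))
        rho, r, *_ = correlate_with_comparison(pd.Series(x, index=degs), rec)
        assert 0.6 < r < 0.95


class TestInputAsReference:
    def test_self_recovery(self, small_compendium):
        comp, _ = small_compendium
        rec = comp.comparisons[2]
        table = input_as_reference(sorted(rec.deg_genes()), comp)
        assert table.iloc[0]["comparison"] == rec.id

    def test_disjoint_user_list_all_p_one(self, small_compendium):
        comp, _ = small_compendium
        table = input_as_reference([f"ALIEN{i}" for i in range(10)], comp)
        assert (table["pvalue"] == 1.0).all()

    def test_matches_naive_oracle(self, small_compendium):
        comp, truth = small_compendium
        user = sorted(truth.de_genes)[:25]
        table = input_as_reference(user, comp).set_index("comparison")
        bg = frozenset(comp.universe) | frozenset(user)
        for rec in list(comp)[:5]:
            expect = ranked_hypergeometric(
                rec.ranked_degs(), frozenset(user), bg
            )
            assert table.loc[rec.id, "pvalue"] == pytest.approx(expect.pvalue)


class TestGenesOnlyAndReports:
    def test_genesonly_matches_full_deg_channel(self, small_compendium):
        comp, truth = small_compendium
        q = prepare_ordered(sorted(truth.de_genes))
        full = deet_enrich(q, comp)
        go = enrich_genesonly(q, comp)
        pd.testing.assert_frame_equal(full.deg_overlap, go.deg_overlap)
        assert len(go.user_pathways) == 0

    def test_report_tables_shapes_and_scatter_classes(self, small_compendium):
        comp, truth = small_compendium
        rec = comp[truth.planted_match]
        degs = sorted(rec.deg_genes())[:20]
        coefs = rec.log2fc_series().loc[degs]
        q = prepare_user_input(degs, [0.01] * len(degs), list(coefs))
        rep = deet_enrich(q, comp)
        tables = report_tables(
            rep, top_n=5, scatter_comparison=rec.id, compendium=comp, query=q
        )
        assert len(tables["deg_overlap"]) <= 5
        assert "neg_log10_fdr" in tables["deg_overlap"].columns
        scatter = tables["scatter"]
        both = scatter.dropna(subset=["user_coefficient", "comparison_log2fc"])
        assert (both["agreement"] == "same-sign").all()
        assert (scatter["agreement"] == "one-only").sum() > 0

    def test_empty_report_yields_empty_tables(self, small_compendium):
        comp, _ = small_compendium
        rep = deet_enrich(prepare_unordered(["ALIEN"]), comp)
        tables = report_tables(rep, top_n=15)
        assert len(tables["correlations"]) == 0


class TestOverlapStats:
    def test_printed_table_arithmetic(self):
        # 35 shared, 40 study-only: 35/40 = 87.5% of study DEGs captured
        study = {f"s{i}" for i in range(75)}
        mine = {f"s{i}" for i in range(35)} | {f"d{i}" for i in range(782)}
        out = overlap_stats(study, mine)
        assert out["intersecting"] == 35
        assert out["study_specific"] == 40
        assert out["compendium_specific"] == 782
        assert out["genes_captured_pct"] == pytest.approx(87.5)
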