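import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from degatlas.analytics import (
    annotate_clusters,
    cluster_comparisons,
    de_prior,
    median_cluster_overlap,
    pairwise_comparison_correlation,
    prior_overlap_curve,
)
from degatlas.core import Compendium, ComparisonRecord, make_deg_table
from degatlas.simulate import simulate_compendium, simulate_genesets


def _record(comp_id, genes, fdrs, lfcs, detected=None):
    tab = make_deg_table(genes, lfcs, np.clip(np.asarray(fdrs) * 0.5, 1e-12, 1), fdr=fdrs)
    return ComparisonRecord(
        id=comp_id,
        name=comp_id,
        source="synthetic",
        category="",
        deg_table=tab,
        detected_genes=frozenset(detected if detected is not None else genes),
    )


class TestPairwiseCorrelation:
    def test_symmetry_diagonal_and_range(self, small_compendium):
        comp, _ = small_compendium
        M = pairwise_comparison_correlation(comp)
        V = M.to_numpy()
        np.testing.assert_allclose(V, V.T, equal_nan=True)
        np.testing.assert_allclose(np.diag(V), 1.0)
        finite = V[np.isfinite(V)]
        assert ((finite >= 0) & (finite <= 1)).all()

    def test_small_shared_universe_is_missing(self):
        genes_a = [f"a{i}" for i in range(30)]
        genes_b = [f"b{i}" for i in range(30)]
        shared = ["s1", "s2"]
        rng = np.random.default_rng(0)
        recs = [
            _record("A", genes_a + shared, rng.uniform(0.001, 0.04, 32),
                    rng.normal(0, 2, 32)),
            _record("B", genes_b + shared, rng.uniform(0.001, 0.04, 32),
                    rng.normal(0, 2, 32)),
        ]
        M = pairwise_comparison_correlation(Compendium(comparisons=recs))
        assert np.isnan(M.loc["A", "B"])

    def test_perturbed_duplicate_is_highly_correlated(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(200)]
        fdr = np.concatenate(
            [rng.uniform(1e-6, 0.04, 40), rng.uniform(0.06, 1, 160)]
        )
        lfc = rng.normal(0, 2, 200)
        # noise small relative to the FDR spread within the DE set
        noisy = np.clip(fdr + rng.normal(0, 0.002, 200), 1e-9, 1)
        recs = [
            _record("orig", genes, fdr, lfc),
            _record("dup", genes, noisy, lfc),
        ]
        M = pairwise_comparison_correlation(Compendium(comparisons=recs))
        assert M.loc["orig", "dup"] > 0.9


class TestClustering:
    def test_identical_comparisons_cluster_together(self):
        M = pd.DataFrame(
            [[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        labels = cluster_comparisons(M, height=0.5)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_height_zero_gives_singletons(self, small_compendium):
        comp, _ = small_compendium
        M = pairwise_comparison_correlation(comp)
        labels = cluster_comparisons(M, height=0.0)
        assert labels.nunique() == len(comp)

    def test_planted_two_block_structure_recovered(self):
        comp, truth = simulate_compendium(
            n_comparisons=14, n_blocks=2, within_block_shared_fraction=0.9,
            n_genes=1200, seed=21,
        )
        M = pairwise_comparison_correlation(comp)
        labels = cluster_comparisons(M, n_clusters=2)
        ari = adjusted_rand_score(
            truth.planted_clusters[labels.index], labels
        )
        assert ari == 1.0

    def test_input_order_invariance(self, small_compendium):
        comp, _ = small_compendium
        M = pairwise_comparison_correlation(comp)
        labels = cluster_comparisons(M, n_clusters=2)
        perm = list(M.index[::-1])
        labels2 = cluster_comparisons(M.loc[perm, perm], n_clusters=2)
        ari = adjusted_rand_score(labels[labels.index], labels2[labels.index])
        assert ari == 1.0


class TestMedianClusterOverlap:
    def test_identical_lists_share_everything(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(50)]
        fdr = np.concatenate([np.full(20, 0.01), np.full(30, 0.5)])
        lfc = rng.normal(0, 2, 50)
        recs = [_record(f"c{k}", genes, fdr, lfc) for k in range(3)]
        labels = pd.Series([1, 1, 1], index=[r.id for r in recs])
        out = median_cluster_overlap(Compendium(comparisons=recs), labels)
        assert out[1] == pytest.approx(1.0)

    def test_half_shared_lists(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(60)]
        lfc = rng.normal(0, 2, 60)
        fdr_a = np.where(np.arange(60) < 10, 0.01, 0.5)  # DEGs g0..g9
        fdr_b = np.where((np.arange(60) >= 5) & (np.arange(60) < 15), 0.01, 0.5)
        recs = [
            _record("A", genes, fdr_a, lfc),
            _record("B", genes, fdr_b, lfc),
        ]
        labels = pd.Series([1, 1], index=["A", "B"])
        out = median_cluster_overlap(Compendium(comparisons=recs), labels)
        assert out[1] == pytest.approx(0.5)

    def test_disjoint_lists_and_singleton(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(40)]
        lfc = rng.normal(0, 2, 40)
        fdr_a = np.where(np.arange(40) < 10, 0.01, 0.5)
        fdr_b = np.where(np.arange(40) >= 30, 0.01, 0.5)
        recs = [
            _record("A", genes, fdr_a, lfc),
            _record("B", genes, fdr_b, lfc),
        ]
        labels = pd.Series([1, 1], index=["A", "B"])
        out = median_cluster_overlap(Compendium(comparisons=recs), labels)
        assert out[1] == pytest.approx(0.0)
        singleton = median_cluster_overlap(
            Compendium(comparisons=recs[:1]), pd.Series([1], index=["A"])
        )
        assert np.isnan(singleton[1])


class TestClusterAnnotation:
    def test_planted_set_is_top_term(self, small_compendium):
        comp, truth = small_compendium
        members = [c for c in comp if c.category == "block0"]
        core = frozenset.intersection(*(c.deg_genes() for c in members))
        db = simulate_genesets(
            n_sets=15, size_range=(15, 60), universe=sorted(comp.universe),
            planted_in=sorted(core), seed=5,
        )
        labels = pd.Series(
            [1 if c.category == "block0" else 2 for c in comp],
            index=[c.id for c in comp],
        )
        ann = annotate_clusters(comp, labels, db)
        assert ann[1][0].term_id == "PLANTED"

    def test_single_member_cluster_reduces_to_own_enrichment(
        self, small_compendium
    ):
        comp, _ = small_compendium
        rec = comp.comparisons[0]
        db = simulate_genesets(
            n_sets=10, size_range=(15, 60), universe=sorted(comp.universe),
            planted_in=sorted(rec.deg_genes())[:30], seed=6,
        )
        labels = pd.Series([1], index=[rec.id])
        sub = Compendium(comparisons=[rec])
        ann = annotate_clusters(sub, labels, db)
        assert ann[1][0].term_id == "PLANTED"


class TestDePrior:
    def test_frequencies_match_naive_count(self, small_compendium):
        comp, _ = small_compendium
        prior = de_prior(comp)
        rng = np.random.default_rng(7)
        for g in rng.choice(prior.index, 25, replace=False):
            n_de = sum(g in c.deg_genes() for c in comp)
            n_det = sum(g in c.detected_genes for c in comp)
            assert prior.loc[g, "de_frequency"] == pytest.approx(n_de / n_det)

    def test_extremes(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(30)]
        fdr = np.where(np.arange(30) < 10, 0.01, 0.5)  # always-DE g0..g9
        recs = [
            _record(f"c{k}", genes, fdr, rng.normal(0, 2, 30))
            for k in range(4)
        ]
        prior = de_prior(Compendium(comparisons=recs))
        always = prior.loc[[f"g{i}" for i in range(10)], "de_frequency"]
        never = prior.loc[[f"g{i}" for i in range(10, 30)], "de_frequency"]
        assert (always == 1.0).all() and (never == 0.0).all()
        assert set(prior["rank"].head(10).index) == set(always.index)

    def test_rank_is_dense_and_consistent(self, small_compendium):
        comp, _ = small_compendium
        prior = de_prior(comp)
        assert list(prior["rank"]) == list(range(1, len(prior) + 1))
        assert prior["de_frequency"].is_monotonic_decreasing


class TestPriorOverlapCurve:
    def test_self_overlap_is_maximal(self, small_compendium):
        comp, _ = small_compendium
        prior = de_prior(comp)
        curve = prior_overlap_curve(prior, prior, step=0.1)
        mid = curve[(curve["q"] > 0.05) & (curve["q"] < 0.95)]
        assert (mid["n_overlap"] == [max(1, int(round(q * len(prior)))) for q in mid["q"]]).all()
        assert (mid["pvalue"] < 1e-10).all()

    def test_final_increment_degenerate(self, small_compendium):
        comp, _ = small_compendium
        prior = de_prior(comp)
        curve = prior_overlap_curve(prior, prior, step=0.25)
        last = curve.iloc[-1]
        assert np.isnan(last["odds_ratio"]) and last["pvalue"] == 1.0

    def test_independent_priors_have_neutral_odds(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(2000)]
        ors = []
        for s in range(20):
            a = pd.DataFrame(
                {"de_frequency": rng.uniform(size=2000)}, index=genes
            ).sort_values("de_frequency", ascending=False)
            a["rank"] = np.arange(1, 2001)
            b = pd.DataFrame(
                {"de_frequency": rng.uniform(size=2000)}, index=genes
            ).sort_values("de_frequency", ascending=False)
            b["rank"] = np.arange(1, 2001)
            curve = prior_overlap_curve(a, b, step=0.1)
            ors.append(curve.loc[np.isclose(curve["q"], 0.1), "odds_ratio"].iloc[0])
        assert 0.8 <= np.median(ors) <= 1.25
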