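import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

from gravipath.dataio import GeneSet, GeneSetCollection
from gravipath.gsea import (
    GSEA,
    DegenerateSetError,
    NoOverlapError,
    RunningSum,
    _es_from_hit_ranks,
    enrichment_score,
    fdr_q,
    filter_significant,
    leading_edge,
    nominal_p,
    normalize_es,
    permutation_null,
    run_gsea,
)
from gravipath.ranking import RankedGeneList
from gravipath.synthetic_data import generate_gsea_fixture

from conftest import random_rgl


class TestEnrichmentScore:
    def test_worked_running_sum(self, five_gene_rgl):
        run = enrichment_score(five_gene_rgl, {"g1", "g3"}, p_weight=1.0)
        np.testing.assert_allclose(
            run.deviations, [0.75, 0.75 - 1 / 3, 2 / 3, 1 / 3, 0.0]
        )
        assert run.es == 0.75
        assert run.peak_index == 1
        assert run.n_hits == 2
        assert run.n_r == 4.0

    def test_single_hit_at_top_scores_one(self, five_gene_rgl):
        run = enrichment_score(five_gene_rgl, {"g1"}, p_weight=1.0)
        assert run.es == 1.0
        assert run.peak_index == 1

    def test_bottom_set_negative_extreme(self):
        rgl = RankedGeneList(
            ["g1", "g2", "g3", "g4"], np.array([2.0, 1.0, -1.0, -2.0])
        )
        run = enrichment_score(rgl, {"g4"}, p_weight=1.0)
        np.testing.assert_allclose(
            run.deviations, [-1 / 3, -2 / 3, -1.0, 0.0]
        )
        assert run.es == -1.0
        assert run.peak_index == 3

    def test_no_overlap_rejected(self, five_gene_rgl):
        with pytest.raises(NoOverlapError):
            enrichment_score(five_gene_rgl, {"absent"})

    def test_full_coverage_rejected(self, five_gene_rgl):
        with pytest.raises(DegenerateSetError):
            enrichment_score(
                five_gene_rgl, {"g1", "g2", "g3", "g4", "g5"}
            )

    @given(seed=st.integers(0, 100_000))
    def test_running_sum_conservation(self, seed):
        """Both cumulative probabilities end at 1, so D_N = 0 exactly and
        the extreme deviation is bounded by 1."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 60))
        rgl = random_rgl(rng, n)
        m = int(rng.integers(1, n))
        members = {f"g{i}" for i in rng.choice(n, m, replace=False)}
        run = enrichment_score(rgl, members, p_weight=rng.choice([0.0, 1.0, 2.0]))
        assert run.deviations[-1] == 0.0
        assert abs(run.es) <= 1.0

    @given(seed=st.integers(0, 100_000))
    def test_hits_only_shortcut_matches_full_trace(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 80))
        rgl = random_rgl(rng, n)
        m = int(rng.integers(1, n))
        hits = np.sort(rng.choice(n, m, replace=False))
        full = enrichment_score(rgl, {f"g{i}" for i in hits}, p_weight=1.0)
        fast = _es_from_hit_ranks(
            np.abs(rgl.metric_values), hits, n
        )
        assert fast == full.es

    def test_zero_weight_reduces_to_rank_ks(self):
        """With p_weight = 0 the statistic ignores metric magnitudes."""
        rng = np.random.default_rng(3)
        rgl = random_rgl(rng, 30)
        members = {f"g{i}" for i in rng.choice(30, 7, replace=False)}
        es1 = enrichment_score(rgl, members, p_weight=0.0).es
        # same ranking, different metric magnitudes
        other = RankedGeneList(
            rgl.gene_ids, np.sort(rng.uniform(-5, 5, 30))[::-1]
        )
        es2 = enrichment_score(other, members, p_weight=0.0).es
        assert es1 == pytest.approx(es2, abs=1e-12)


class TestLeadingEdge:
    def test_positive_peak_members_before_peak(self, five_gene_rgl):
        run = enrichment_score(five_gene_rgl, {"g1", "g3"})
        assert leading_edge(run, five_gene_rgl, {"g1", "g3"}) == ["g1"]

    def test_negative_peak_members_from_peak_on(self):
        rgl = RankedGeneList(
            ["g1", "g2", "g3", "g4"], np.array([2.0, 1.0, -1.0, -2.0])
        )
        run = enrichment_score(rgl, {"g4"})
        assert leading_edge(run, rgl, {"g4"}) == ["g4"]

    def test_whole_set_when_peak_at_last_hit(self, five_gene_rgl):
        members = {"g1", "g2"}
        run = enrichment_score(five_gene_rgl, members)
        le = leading_edge(run, five_gene_rgl, members)
        assert le == ["g1", "g2"]

    def test_zero_es_gives_empty_leading_edge(self, five_gene_rgl):
        run = RunningSum(
            deviations=np.zeros(5), es=0.0, peak_index=1, n_hits=1,
            n_r=1.0, p_weight=1.0,
        )
        assert leading_edge(run, five_gene_rgl, {"g1"}) == []

    def test_order_follows_ranked_list(self):
        rng = np.random.default_rng(11)
        rgl = random_rgl(rng, 40)
        members = {f"g{i}" for i in rng.choice(40, 10, replace=False)}
        run = enrichment_score(rgl, members)
        le = leading_edge(run, rgl, members)
        ranks = [rgl.rank(g) for g in le]
        assert ranks == sorted(ranks)
        assert set(le) <= members


class TestPermutationNull:
    def test_same_seed_reproduces(self, five_gene_rgl):
        a = permutation_null(five_gene_rgl, 2, n_perm=50, seed=5)
        b = permutation_null(five_gene_rgl, 2, n_perm=50, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_set_size_must_be_below_universe(self, five_gene_rgl):
        with pytest.raises(DegenerateSetError):
            permutation_null(five_gene_rgl, 5, n_perm=10, seed=0)

    def test_null_es_bounded(self):
        rng = np.random.default_rng(0)
        rgl = random_rgl(rng, 40)
        null = permutation_null(rgl, 8, n_perm=200, seed=1)
        assert np.all(np.abs(null) <= 1.0)

    def test_observed_quantile_uniform_under_null(self):
        """On exchangeable data the nominal p of a fixed set is uniform
        across replicate datasets (KS test at the 1% level)."""
        from scipy.stats import kstest

        ps = []
        rng = np.random.default_rng(2024)
        for _ in range(300):
            r = np.sort(rng.normal(size=60))[::-1]
            rgl = RankedGeneList([f"g{i}" for i in range(60)], r)
            members = {f"g{i}" for i in rng.choice(60, 10, replace=False)}
            es = enrichment_score(rgl, members).es
            null = permutation_null(rgl, 10, n_perm=100, seed=rng)
            ps.append(nominal_p(es, null))
        assert kstest(ps, "uniform").pvalue > 0.01


class TestNominalP:
    def test_more_extreme_than_all_positive_nulls(self):
        null = np.abs(np.random.default_rng(0).normal(size=1000)) * 0.1
        assert nominal_p(0.99, null) == 1 / 1001

    def test_less_extreme_than_all_nulls(self):
        null = np.linspace(0.5, 0.9, 100)
        assert nominal_p(0.1, null) == 1.0

    def test_at_median_of_same_sign_null(self):
        null = np.linspace(0.01, 0.99, 99)  # all positive, median 0.5
        assert nominal_p(0.5, null) == pytest.approx(0.51, abs=0.01)

    def test_negative_side_mirrors(self):
        null = np.concatenate([np.linspace(-0.9, -0.1, 50), np.linspace(0.1, 0.9, 50)])
        assert nominal_p(-0.95, null) == nominal_p(0.95, -null)


class TestNormalizeEs:
    def test_self_normalisation(self):
        assert normalize_es(0.4, np.full(10, 0.4)) == pytest.approx(1.0)

    def test_worked_example(self):
        assert normalize_es(0.8, np.array([0.2, 0.6])) == pytest.approx(2.0)

    def test_sign_preserved_under_negation(self):
        null = np.array([0.2, -0.3, 0.5, -0.6])
        assert normalize_es(-0.4, -null) == pytest.approx(
            -normalize_es(0.4, null)
        )

    def test_no_same_sign_null_flagged_nan(self):
        assert np.isnan(normalize_es(0.5, np.array([-0.1, -0.2])))


class TestFdrQ:
    def test_point_mass_null_gives_one(self):
        q = fdr_q([1.5], np.full(100, 1.5))
        assert q[0] == 1.0

    def test_null_never_as_extreme_gives_zero(self):
        q = fdr_q([3.0], np.random.default_rng(0).normal(size=500) * 0.1)
        assert q[0] == 0.0

    def test_monotone_along_nes_ordering(self):
        rng = np.random.default_rng(1)
        obs = np.sort(rng.normal(size=20))[::-1]
        null = rng.normal(size=2000)
        q = fdr_q(obs, null)
        pos = obs >= 0
        assert np.all(np.diff(q[pos]) >= 0)  # obs sorted descending
        neg = obs < 0
        assert np.all(np.diff(q[neg]) <= 0)

    def test_planted_sets_take_smallest_q(self):
        """End-to-end: the 5 planted sets of the default fixture receive
        the 5 smallest q values."""
        ds, labels, coll, truth = generate_gsea_fixture(seed=0)
        res = run_gsea(ds, labels, coll, n_perm=500, random_state=0)
        smallest = set(res.nsmallest(5, "q_fdr")["set_name"])
        assert smallest == set(truth.planted_up_sets)

    def test_nan_nes_excluded(self):
        q = fdr_q([1.0, np.nan], np.random.default_rng(0).normal(size=100))
        assert np.isfinite(q[0]) and np.isnan(q[1])


class TestRunGsea:
    def test_planted_up_set_ranks_first(self):
        ds, labels, coll, truth = generate_gsea_fixture(
            n_genes=600, n_sets=15, set_size=25, n_planted=1, seed=4
        )
        res = run_gsea(ds, labels, coll, n_perm=300, random_state=4)
        assert res.iloc[0]["set_name"] in truth.planted_up_sets

    def test_empty_collection_gives_empty_table(self, tiny_dataset, tiny_labels):
        res = run_gsea(
            tiny_dataset, tiny_labels, GeneSetCollection([], "none"),
            n_perm=10, random_state=0,
        )
        assert len(res) == 0
        assert list(res.columns) == [
            "set_name", "module", "size", "ES", "NES",
            "p_nominal", "q_fdr", "peak_index", "leading_edge",
        ]

    def test_size_window_skips_sets(self):
        ds, labels, coll, _ = generate_gsea_fixture(
            n_genes=300, n_sets=8, set_size=20, n_planted=0, seed=1
        )
        res = run_gsea(
            ds, labels, coll, n_perm=20, min_size=25, max_size=500,
            random_state=0,
        )
        assert len(res) == 0

    def test_deterministic_under_fixed_seed(self):
        ds, labels, coll, _ = generate_gsea_fixture(
            n_genes=300, n_sets=6, set_size=15, n_planted=1, seed=2
        )
        r1 = run_gsea(ds, labels, coll, n_perm=100, random_state=9)
        r2 = run_gsea(ds, labels, coll, n_perm=100, random_state=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_null_dataset_rarely_significant(self):
        """With identical group distributions, no set should pass the
        reporting filter in the vast majority of seeds."""
        passes = 0
        for seed in range(20):
            ds, labels, coll, _ = generate_gsea_fixture(
                effect_size=0.0, n_genes=600, n_sets=12, set_size=25,
                seed=300 + seed,
            )
            res = run_gsea(ds, labels, coll, n_perm=200, random_state=seed)
            up, down = filter_significant(res, 0.01, 0.25)
            passes += (len(up) + len(down)) > 0
        assert passes <= 1

    def test_phenotype_permutation_scheme(self):
        ds, labels, coll, truth = generate_gsea_fixture(
            n_genes=200, n_per_group=4, n_sets=4, set_size=20,
            n_planted=1, seed=5,
        )
        res = run_gsea(
            ds, labels, coll, n_perm=50, permutation="phenotype",
            min_size=5, random_state=5,
        )
        assert len(res) == 4
        assert res.iloc[0]["set_name"] in truth.planted_up_sets

    def test_bh_fdr_option(self):
        ds, labels, coll, _ = generate_gsea_fixture(
            n_genes=300, n_sets=6, set_size=20, n_planted=1, seed=6
        )
        res = run_gsea(
            ds, labels, coll, n_perm=100, fdr_method="bh", random_state=6
        )
        assert res["q_fdr"].between(0, 1).all()


class TestGseaEstimator:
    def test_sklearn_param_interface(self):
        est = GSEA(n_perm=123, p_weight=0.0)
        assert est.get_params()["n_perm"] == 123
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        cloned.set_params(min_size=3)
        assert cloned.min_size == 3

    def test_fit_attaches_results(self):
        ds, labels, coll, _ = generate_gsea_fixture(
            n_genes=200, n_sets=4, set_size=20, n_planted=1, seed=7
        )
        est = GSEA(n_perm=50, random_state=0).fit(ds, labels, coll)
        assert hasattr(est, "results_") and hasattr(est, "ranked_list_")
        assert est.ranked_list_.n == 200


class TestFilterSignificant:
    @pytest.fixture
    def table(self):
        return pd.DataFrame(
            {
                "set_name": ["a", "b", "c"],
                "NES": [1.8, -1.5, 1.2],
                "p_nominal": [0.005, 0.003, 0.02],
                "q_fdr": [0.1, 0.2, 0.1],
                "leading_edge": [["x"], ["y"], ["z"]],
            }
        )

    def test_threshold_application(self, table):
        up, down = filter_significant(table, 0.01, 0.25)
        assert list(up["set_name"]) == ["a"]
        assert list(down["set_name"]) == ["b"]

    def test_identity_filter(self, table):
        up, down = filter_significant(table, 1.1, 1.1)
        assert len(up) + len(down) == 3
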