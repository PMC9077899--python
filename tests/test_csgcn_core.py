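import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.mixture import GaussianMixture

from csgcnreg import csgcn_core as cc
from csgcnreg import synthetic_data as sd
from csgcnreg.gem_io import GEM, LOG2, SampleAnnotation


def _series(values, prefix="s", name="g"):
    return pd.Series(
        values, index=[f"{prefix}{i}" for i in range(len(values))], name=name
    )


class TestPrefilter:
    def test_out_of_range_value_excluded(self):
        x = _series([1.0, 15.2, 3.0])
        y = _series([2.0, 2.0, 2.0], name="h")
        assert list(cc.prefilter_values(x, y)) == ["s0", "s2"]

    def test_all_in_range_is_identity(self):
        x = _series([1.0, 2.0, 3.0])
        y = _series([4.0, 5.0, 6.0], name="h")
        assert list(cc.prefilter_values(x, y)) == ["s0", "s1", "s2"]

    def test_matches_brute_force_on_random_mask(self, rng):
        x = _series(rng.uniform(-2, 17, size=200))
        y = _series(rng.uniform(-2, 17, size=200), name="h")
        x[rng.random(200) < 0.2] = np.nan
        y[rng.random(200) < 0.2] = np.nan
        expected = [
            s
            for s in x.index
            if np.isfinite(x[s])
            and np.isfinite(y[s])
            and 0 <= x[s] <= 15
            and 0 <= y[s] <= 15
        ]
        assert list(cc.prefilter_values(x, y)) == expected


class TestPairGmm:
    def test_single_gaussian_selects_k1(self, rng):
        z = rng.multivariate_normal([5, 5], [[1, 0.5], [0.5, 1]], size=200)
        clusters = cc.fit_pair_gmm(_series(z[:, 0]), _series(z[:, 1], name="h"), seed=3)
        assert clusters and clusters[0].k_selected == 1

    def test_k_selection_equals_brute_force_min_bic(self, rng):
        """k chosen by the pipeline equals an independent argmin-BIC sweep."""
        for seed in range(4):
            r = np.random.default_rng(seed)
            data = np.vstack(
                [
                    r.normal([3, 3], 0.7, size=(80, 2)),
                    r.normal([9, 9], 0.7, size=(80, 2)),
                ]
            )
            x = _series(data[:, 0])
            y = _series(data[:, 1], name="h")
            clusters = cc.fit_pair_gmm(x, y, seed=seed)
            bics = []
            for k in range(1, 6):
                gm = GaussianMixture(
                    n_components=k,
                    covariance_type="full",
                    init_params="k-means++",
                    random_state=seed,
                    reg_covar=1e-6,
                ).fit(data)
                bics.append(gm.bic(data))
            assert clusters[0].k_selected == int(np.argmin(bics)) + 1

    def test_separated_components_recovered(self, rng):
        # two planted components 6 sigma apart: k=2, >=95% label agreement
        a = rng.normal([2, 2], 1.0, size=(100, 2))
        b = rng.normal([8, 8], 1.0, size=(100, 2))
        data = np.vstack([a, b])
        x = _series(data[:, 0])
        y = _series(data[:, 1], name="h")
        clusters = cc.fit_pair_gmm(x, y, seed=0)
        assert clusters[0].k_selected == 2
        assert len(clusters) == 2
        planted_first = set(x.index[:100])
        agreements = []
        for cl in clusters:
            members = set(cl.member_samples)
            inside = len(members & planted_first) / len(members)
            agreements.append(max(inside, 1 - inside))
        assert min(agreements) >= 0.95

    def test_min_size_rule_skips_pair(self, rng):
        x = _series(rng.normal(5, 1, 29))
        y = _series(rng.normal(5, 1, 29), name="h")
        assert cc.fit_pair_gmm(x, y) == []

    def test_small_clusters_discarded(self, rng):
        # 100 + 15 samples: second component (if found) is under min size
        data = np.vstack(
            [rng.normal([3, 3], 0.5, size=(100, 2)), rng.normal([9, 9], 0.5, size=(15, 2))]
        )
        clusters = cc.fit_pair_gmm(
            _series(data[:, 0]), _series(data[:, 1], name="h"), seed=1
        )
        assert all(c.n >= 30 for c in clusters)


class TestClusterSpearman:
    def _cluster(self, x):
        return cc.PairCluster("g", "h", 0, list(x.index), 1)

    def test_monotone_increasing_gives_rho_one(self):
        x = _series(np.arange(40, dtype=float))
        y = _series(np.arange(40, dtype=float) ** 2, name="h")
        out = cc.cluster_spearman(self._cluster(x), x, y)
        assert out is not None and out.spearman_rho == pytest.approx(1.0)

    def test_anticorrelated_gives_rho_minus_one(self):
        x = _series(np.arange(40, dtype=float))
        y = _series(-np.arange(40, dtype=float), name="h")
        out = cc.cluster_spearman(self._cluster(x), x, y)
        assert out is not None and out.spearman_rho == pytest.approx(-1.0)

    def test_weak_planted_correlation_rejected(self, rng):
        # Gaussian copula at Spearman 0.4 stays under the 0.5 threshold
        r = sd.spearman_to_pearson(0.4)
        z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=200)
        x = _series(z[:, 0])
        y = _series(z[:, 1], name="h")
        assert cc.cluster_spearman(self._cluster(x), x, y) is None

    def test_zero_variance_gives_no_candidate(self):
        x = _series(np.ones(40))
        y = _series(np.arange(40, dtype=float), name="h")
        assert cc.cluster_spearman(self._cluster(x), x, y) is None


class TestCorrelationPower:
    def test_limit_r_to_one(self):
        assert cc.correlation_power(4, 1.0) == 1.0
        assert cc.correlation_power(10, 0.9999) > 0.999

    def test_null_r_zero_gives_alpha_level(self):
        assert cc.correlation_power(100, 0.0, alpha=0.001) == pytest.approx(
            0.0005, abs=2e-4
        )

    @pytest.mark.parametrize(
        "n,r,alpha",
        [(100, 0.5, 0.001), (30, 0.5, 0.001), (60, -0.7, 0.001), (200, 0.3, 0.05)],
    )
    def test_matches_fisher_z_closed_form(self, n, r, alpha):
        # independent inline rendering of the closed form
        expected = stats.norm.cdf(
            abs(np.arctanh(r)) * np.sqrt(n - 3) - stats.norm.isf(alpha / 2)
        )
        assert cc.correlation_power(n, r, alpha) == pytest.approx(
            expected, abs=1e-6
        )

    def test_power_monotone_in_n(self):
        powers = [cc.correlation_power(n, 0.5) for n in (10, 30, 100, 300)]
        assert powers == sorted(powers)


def _annotated_cluster(n_in_cond, n_in_other, n_out_cond, n_out_other):
    """Cluster membership crossed with a binary condition label."""
    samples, labels, members = [], [], []
    k = 0
    for count, cond, in_cluster in (
        (n_in_cond, "c", True),
        (n_in_other, "o", True),
        (n_out_cond, "c", False),
        (n_out_other, "o", False),
    ):
        for _ in range(count):
            s = f"s{k}"
            k += 1
            samples.append(s)
            labels.append(cond)
            if in_cluster:
                members.append(s)
    annot = SampleAnnotation(pd.Series(labels, index=samples))
    cluster = cc.PairCluster("g", "h", 0, members, 1)
    return cluster, annot, samples


class TestConditionCategorical:
    def test_pure_condition_cluster_labeled(self):
        cluster, annot, samples = _annotated_cluster(50, 0, 0, 50)
        res = cc.test_condition_categorical(cluster, annot, "c", samples)
        assert res.labeled
        assert res.p_in_cluster < 1e-10 and res.p_capture < 1e-10

    def test_background_composition_not_labeled(self):
        cluster, annot, samples = _annotated_cluster(25, 25, 25, 25)
        res = cc.test_condition_categorical(cluster, annot, "c", samples)
        assert not res.labeled
        assert res.p_in_cluster > 0.4

    def test_depleted_cluster_not_labeled_one_sided(self):
        cluster, annot, samples = _annotated_cluster(5, 45, 45, 5)
        res = cc.test_condition_categorical(cluster, annot, "c", samples)
        assert not res.labeled
        assert res.p_in_cluster > 0.99  # enrichment direction only

    def test_absent_condition_undefined(self):
        cluster, annot, samples = _annotated_cluster(20, 20, 20, 20)
        res = cc.test_condition_categorical(cluster, annot, "zzz", samples)
        assert not res.labeled and np.isnan(res.p_in_cluster)


class TestConditionQuantitative:
    def test_separating_covariate_labeled(self, rng):
        cluster, annot, samples = _annotated_cluster(40, 0, 0, 40)
        cov = pd.Series(
            [10.0 + rng.normal(0, 0.1) for _ in range(40)]
            + [1.0 + rng.normal(0, 0.1) for _ in range(40)],
            index=samples,
        )
        res = cc.test_condition_quantitative(cluster, cov, samples)
        assert res.labeled and res.r_square > 0.9

    def test_independent_covariate_not_labeled(self, rng):
        cluster, annot, samples = _annotated_cluster(40, 0, 0, 40)
        cov = pd.Series(rng.normal(0, 1, size=80), index=samples)
        res = cc.test_condition_quantitative(cluster, cov, samples)
        assert not res.labeled

    def test_r_square_below_threshold_not_labeled(self, rng):
        # moderate association: p tiny but r^2 under 0.30 -> rejected
        cluster, annot, samples = _annotated_cluster(100, 0, 0, 100)
        member = np.array([1.0] * 100 + [0.0] * 100)
        cov = pd.Series(0.5 * member + rng.normal(0, 1.0, 200), index=samples)
        res = cc.test_condition_quantitative(cluster, cov, samples)
        if res.r_square is not None and res.r_square <= 0.30:
            assert not res.labeled

    def test_constant_covariate_not_labeled(self):
        cluster, annot, samples = _annotated_cluster(40, 0, 0, 40)
        cov = pd.Series(np.ones(80), index=samples)
        res = cc.test_condition_quantitative(cluster, cov, samples)
        assert not res.labeled and res.r_square is None


class TestBiasFilters:
    def test_shifted_genes_pass_dce(self, rng):
        cluster, annot, samples = _annotated_cluster(40, 0, 0, 40)
        x = pd.Series(
            np.r_[rng.normal(8, 1, 40), rng.normal(4, 1, 40)], index=samples, name="g"
        )
        y = pd.Series(
            np.r_[rng.normal(9, 1, 40), rng.normal(5, 1, 40)], index=samples, name="h"
        )
        keep, pa, pb = cc.filter_dce(cluster, x, y, samples)
        assert keep and pa < 1e-10 and pb < 1e-10

    def test_flat_gene_fails_dce(self, rng):
        cluster, annot, samples = _annotated_cluster(40, 0, 0, 40)
        x = pd.Series(rng.normal(5, 1, 80), index=samples, name="g")  # no shift
        y = pd.Series(
            np.r_[rng.normal(9, 1, 40), rng.normal(5, 1, 40)], index=samples, name="h"
        )
        keep, pa, _ = cc.filter_dce(cluster, x, y, samples)
        assert not keep and pa > 0.001

    def test_constant_gene_dropped(self):
        cluster, annot, samples = _annotated_cluster(40, 0, 0, 40)
        x = pd.Series(np.ones(80), index=samples, name="g")
        y = pd.Series(np.arange(80, dtype=float), index=samples, name="h")
        keep, pa, _ = cc.filter_dce(cluster, x, y, samples)
        assert not keep and np.isnan(pa)

    def test_no_missingness_kept(self, rng):
        cluster, annot, samples = _annotated_cluster(40, 0, 0, 40)
        x = pd.Series(rng.normal(5, 1, 80), index=samples, name="g")
        y = pd.Series(rng.normal(5, 1, 80), index=samples, name="h")
        keep, p = cc.filter_missingness_bias(cluster, x, y, annot, ["c"])
        assert keep and np.isnan(p)

    def test_one_sided_missingness_dropped(self, rng):
        cluster, annot, samples = _annotated_cluster(40, 0, 0, 40)
        x = pd.Series(rng.normal(5, 1, 80), index=samples, name="g")
        y = pd.Series(rng.normal(5, 1, 80), index=samples, name="h")
        cond_c = annot.samples_of("c")
        hit = rng.random(len(cond_c)) < 0.8
        x.loc[cond_c[hit]] = np.nan  # gene A missing in 80% of condition c
        keep, p = cc.filter_missingness_bias(cluster, x, y, annot, ["c"])
        assert not keep and p < 0.1

    def test_symmetric_missingness_kept_under_null(self):
        kept = 0
        reps = 100
        for rep in range(reps):
            r = np.random.default_rng(rep)
            cluster, annot, samples = _annotated_cluster(40, 0, 0, 40)
            x = pd.Series(r.normal(5, 1, 80), index=samples, name="g")
            y = pd.Series(r.normal(5, 1, 80), index=samples, name="h")
            x[r.random(80) < 0.1] = np.nan
            y[r.random(80) < 0.1] = np.nan
            keep, _ = cc.filter_missingness_bias(cluster, x, y, annot, ["c"])
            kept += keep
        assert kept / reps >= 0.85  # ~= 1 - p_cut under the null


class TestRankEdges:
    def _edge(self, rho, p=1e-5, r2=None):
        cluster = cc.PairCluster("g", "h", 0, [f"s{i}" for i in range(30)], 1)
        res = cc.ConditionTestResult("c", p_in_cluster=p, p_capture=p, labeled=True)
        if r2 is not None:
            res.r_square = r2
        return cc.CsgcnEdge("g", "h", cluster, rho, {"c": res}, 0.9)

    def test_similarity_descending(self):
        e1, e2 = self._edge(0.7), self._edge(0.9)
        ranked = cc.rank_edges([e1, e2])
        assert ranked[0].similarity == 0.9 and ranked[0].rank == 1

    def test_p_value_breaks_ties(self):
        e1, e2 = self._edge(0.8, p=1e-4), self._edge(0.8, p=1e-8)
        ranked = cc.rank_edges([e1, e2])
        assert ranked[0].conditions["c"].p_in_cluster == 1e-8

    def test_ranking_is_a_permutation(self):
        edges = [self._edge(r) for r in (0.6, 0.9, -0.7, 0.55)]
        ranked = cc.rank_edges(list(edges))
        assert sorted(e.rank for e in ranked) == [1, 2, 3, 4]
        assert {id(e) for e in ranked} == {id(e) for e in edges}


class TestBuildCsgcn:
    def test_retained_edges_satisfy_all_thresholds(self, planted_edges_built):
        edges, _ = planted_edges_built
        assert edges
        for e in edges:
            assert abs(e.similarity) > 0.5
            assert e.power >= 0.8
            assert e.labeled_conditions
            assert not e.dce_fail and not e.missingness_fail
            assert e.cluster.n >= 30
            for cond in e.labeled_conditions:
                r = e.conditions[cond]
                if r.quantitative:
                    assert r.r_square > 0.30 and r.p_reg < 0.001
                else:
                    assert r.p_in_cluster < 0.001 and r.p_capture < 0.001

    def test_determinism_same_seed_same_edges(self, planted_normalized):
        norm, annot, truth = planted_normalized
        genes = sorted(
            {g for e in truth.planted_edges[:5] for g in (e.gene_a, e.gene_b)}
        )
        p = cc.CsgcnParams(seed=9, genes=genes)
        e1 = cc.build_csgcn(norm, annot, p)
        e2 = cc.build_csgcn(norm, annot, p)
        assert cc.edges_to_frame(e1).equals(cc.edges_to_frame(e2))

    def test_invariant_to_sample_column_order(self, planted_normalized, rng):
        norm, annot, truth = planted_normalized
        genes = sorted(
            {g for e in truth.planted_edges[:4] for g in (e.gene_a, e.gene_b)}
        )
        p = cc.CsgcnParams(seed=9, genes=genes)
        e1 = cc.build_csgcn(norm, annot, p)
        shuffled = norm.subset_samples(list(rng.permutation(norm.sample_ids)))
        e2 = cc.build_csgcn(shuffled, annot, p)
        assert cc.edges_to_frame(e1).equals(cc.edges_to_frame(e2))

    def test_null_bundle_yields_no_labeled_edges(self):
        spec = sd.TruthSpec(
            n_planted_edges=0, n_grn_edges=0, n_degs=0, n_triangle_tfs=0
        )
        gem, annot, _ = sd.generate_dataset(
            20, {"a": 60, "b": 60}, spec, seed=13
        )
        from csgcnreg.gem_io import log2_quantile_normalize

        norm = log2_quantile_normalize(gem)
        edges = cc.build_csgcn(norm, annot, cc.CsgcnParams(seed=13))
        # 190 pairs at alpha 0.001 on two tests: expect ~0 labeled edges
        assert len(edges) <= 2
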