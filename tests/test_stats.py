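import numpy as np
import pytest
from scipy import stats as sps

from coralmet.preprocess import log_intensities, scale
from coralmet.stats import (
    OPLSDA,
    adjust_pvalues,
    compute_vip,
    cross_validate,
    fit_oplsda,
    fit_pca,
    gated_test,
    gated_tests_matrix,
    pathway_ora,
    permutation_test,
    screen_differential,
    shannon_diversity,
    stratified_folds,
    venn_counts,
)


class TestGatedTest:
    def test_identical_samples_give_p_near_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = gated_test(x, x.copy())
        assert res.p_value > 0.95

    def test_separated_normal_samples_use_t_test(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 1.0, 8)
        y = rng.normal(10.0, 1.0, 4)
        res = gated_test(x, y)
        assert res.test_used == "t_test"
        assert res.p_value < 0.01

    def test_heavy_tailed_data_routes_to_mann_whitney(self):
        # a fixture that decisively fails Shapiro-Wilk in group 1
        x = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1000.0])
        y = np.array([2.0, 2.5, 3.0, 3.5])
        assert sps.shapiro(x).pvalue < 0.05
        res = gated_test(x, y)
        assert res.test_used == "mann_whitney"

    def test_constant_input_flagged_with_p_one(self):
        res = gated_test([5.0] * 4, [5.0] * 4)
        assert res.p_value == 1.0
        assert res.flag == "constant input"

    def test_requires_three_per_group(self):
        with pytest.raises(ValueError):
            gated_test([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_log_transform_matrix_routes_lognormal_to_t(self):
        rng = np.random.default_rng(1)
        X = rng.lognormal(mean=10, sigma=0.2, size=(12, 40))
        y = np.array([0] * 8 + [1] * 4)
        res = gated_tests_matrix(X, y, log_transform=True)
        frac_t = np.mean([r.test_used == "t_test" for r in res])
        assert frac_t > 0.8


class TestAdjustPvalues:
    def test_hand_computed_step_up(self):
        # BH on (0.01, 0.02, 0.03): 0.01*3/1=0.03, 0.02*3/2=0.03, 0.03*3/3
        assert adjust_pvalues([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_equal_pvalues_unchanged(self):
        assert adjust_pvalues([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_single_p_identity_and_monotone(self):
        assert adjust_pvalues([0.04]) == pytest.approx([0.04])
        p = np.array([0.001, 0.5, 0.04, 0.2])
        adj = adjust_pvalues(p)
        assert (adj >= p).all()


class TestPca:
    def test_rank_one_matrix_pc1_explains_everything(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([1.0, -1.0, 0.5])
        X = np.outer(u, v)
        res = fit_pca(X - X.mean(axis=0), n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_scores_are_orthogonal(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 6))
        res = fit_pca(scale(X).values)
        assert res.scores[:, 0] @ res.scores[:, 1] == pytest.approx(0.0, abs=1e-8)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.ones((2, 5)), n_components=3)

    def test_planted_groups_separate_on_pc1(self, seed42_dataset):
        from sklearn.metrics import silhouette_score

        from coralmet.preprocess import analysis_matrix

        _s, table, _g = seed42_dataset
        X, y = analysis_matrix(table)
        Xs = scale(log_intensities(X.to_numpy(float)), "unit_variance").values
        res = fit_pca(Xs)
        assert silhouette_score(res.scores[:, :1], y) > 0
        assert res.within_ellipse.all()


def _planted(n=12, p=60, n_inf=6, effect=3.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0] * (n - n // 3) + [1] * (n // 3))
    X = rng.normal(size=(n, p))
    X[:, :n_inf] += effect * y[:, None]
    return X, y


class TestOplsda:
    def test_noise_free_single_column_gives_r2y_one(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        X = np.column_stack([y.astype(float), np.ones(8) * 2.0])
        m = fit_oplsda(X - X.mean(axis=0), y, n_orthogonal=0, k_folds=4)
        assert m.r2y_ == pytest.approx(1.0)

    def test_orthogonal_scores_uncorrelated_with_y(self):
        X, y = _planted(seed=3)
        m = OPLSDA(n_orthogonal=2, scale="unit_variance").fit(X, y)
        yc = y - y.mean()
        for t_o in m.orthogonal_scores_:
            assert abs(t_o @ yc) < 1e-8

    def test_vip_largest_on_planted_features(self, seed42_dataset):
        from coralmet.preprocess import analysis_matrix

        _s, table, truth = seed42_dataset
        X, y = analysis_matrix(table)
        m = OPLSDA(scale="pareto").fit(log_intensities(X.to_numpy(float)), y)
        vip = dict(zip(X.columns, m.vip_))
        planted = truth.all_differential_ids & set(X.columns)
        null = set(X.columns) - planted - {truth.internal_standard_id}
        mean_planted = np.mean([vip[f] for f in planted])
        mean_null = np.mean([vip[f] for f in null])
        assert mean_planted > 2 * mean_null
        # top-10 VIP features are all planted
        top = sorted(vip, key=vip.get, reverse=True)[:10]
        assert set(top) <= planted

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            OPLSDA().fit(np.ones((4, 3)), [1, 1, 1, 1])

    def test_q2_bounded_by_r2y_on_signal(self):
        for seed in range(3):
            X, y = _planted(seed=seed)
            m = OPLSDA(scale="unit_variance", random_state=seed).fit(X, y)
            assert m.q2_ <= m.r2y_ + 1e-9

    def test_predict_recovers_training_labels_on_separable_data(self):
        X, y = _planted(effect=5.0, seed=4)
        m = OPLSDA(scale="unit_variance").fit(X, y)
        assert (m.predict(X) == y).all()

    def test_sklearn_param_interface(self):
        m = OPLSDA(max_ortho=3, scale="pareto")
        assert m.get_params()["max_ortho"] == 3
        m.set_params(k_folds=4)
        assert m.k_folds == 4


class TestVip:
    def test_mean_square_is_one_on_every_fit(self):
        for seed in range(5):
            X, y = _planted(seed=seed, p=30)
            m = OPLSDA(scale="unit_variance", random_state=seed).fit(X, y)
            assert (m.vip_**2).mean() == pytest.approx(1.0, abs=1e-10)
            total = compute_vip(m, variant="total")
            assert (total**2).mean() == pytest.approx(1.0, abs=1e-10)

    def test_single_informative_variable_vip_sqrt_p(self):
        rng = np.random.default_rng(5)
        y = np.array([0] * 6 + [1] * 6)
        p = 16
        X = rng.normal(0, 1e-6, size=(12, p))
        X[:, 0] = y * 2.0
        m = fit_oplsda(X - X.mean(axis=0), y, n_orthogonal=0, k_folds=4)
        assert m.vip_[0] == pytest.approx(np.sqrt(p), rel=1e-4)
        assert (m.vip_[1:] < 0.01).all()

    def test_equal_weights_give_unit_vip(self):
        y = np.array([0.0, 0, 0, 1, 1, 1])
        X = np.tile(y[:, None], (1, 5))  # every column identical to y
        m = fit_oplsda(X - X.mean(axis=0), y, n_orthogonal=0, k_folds=3)
        assert m.vip_ == pytest.approx(np.ones(5))


class TestCrossValidation:
    def test_folds_are_stratified_and_deterministic(self):
        y = np.array([0] * 8 + [1] * 4)
        f1 = stratified_folds(y, 7, seed=1)
        f2 = stratified_folds(y, 7, seed=1)
        assert all((a == b).all() for a, b in zip(f1, f2))
        assert sorted(i for f in f1 for i in f) == list(range(12))
        assert max(len(f) for f in f1) - min(len(f) for f in f1) <= 1

    def test_k_equal_n_is_leave_one_out(self):
        y = np.array([0] * 4 + [1] * 4)
        folds = stratified_folds(y, 8, seed=0)
        assert sorted(len(f) for f in folds) == [1] * 8

    def test_pure_noise_gives_nonpositive_q2(self):
        rng = np.random.default_rng(6)
        q2s = []
        for seed in range(10):
            X = rng.normal(size=(12, 30))
            y = np.array([0] * 8 + [1] * 4)
            q2s.append(cross_validate(X, y, k=7, n_ortho=0, seed=seed))
        assert np.mean(q2s) <= 0

    def test_separable_data_gives_q2_near_one(self):
        rng = np.random.default_rng(7)
        y = np.array([0] * 8 + [1] * 4)
        X = rng.normal(size=(12, 20))
        X[:, :10] += 6.0 * y[:, None]  # half the variables carry the split
        q2 = cross_validate(X, y, k=7, n_ortho=0, scale="unit_variance", seed=0)
        assert q2 > 0.9


class TestPermutation:
    def test_identity_permutation_reproduces_observed(self):
        X, y = _planted(effect=4.0, seed=8)
        m = OPLSDA(scale="unit_variance", random_state=0).fit(X, y)
        q2_same = cross_validate(
            X, y, k=7, n_ortho=m.n_orthogonal_, scale="unit_variance", seed=0
        )
        assert q2_same == pytest.approx(m.q2_)

    def test_planted_signal_never_beaten_by_permutations(self):
        X, y = _planted(n=12, p=40, n_inf=8, effect=4.0, seed=9)
        res = permutation_test(X, y, n_perm=30, seed=1, scale="unit_variance")
        assert res.p_empirical == pytest.approx(1.0 / 31.0)
        assert res.q2_perm.mean() < res.observed_q2
        assert res.q2_intercept < res.observed_q2

    def test_label_independent_data_gives_large_p(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(12, 20))
            y = np.array([0] * 8 + [1] * 4)
            res = permutation_test(X, y, n_perm=30, seed=seed,
                                   scale="unit_variance")
            hits += res.p_empirical > 0.05
        assert hits >= 9

    def test_few_permutations_warn(self):
        X, y = _planted(seed=10)
        with pytest.warns(UserWarning):
            permutation_test(X, y, n_perm=5, seed=0, scale="unit_variance")


class TestScreening:
    def test_joint_criteria(self):
        res, counts = screen_differential(
            ["f1", "f2"], [1.2, 0.8], [0.01, 0.01], [10, 5], [1, 50]
        )
        assert [r.significant for r in res] == [True, False]
        assert res[0].direction == "higher_in_A"
        assert counts["total_significant"] == 1

    def test_summary_counts_sum(self):
        n = 350
        rng = np.random.default_rng(11)
        vip = np.full(n, 1.5)
        p = np.full(n, 0.001)
        mean_a = np.zeros(n)
        mean_b = np.zeros(n)
        idx = rng.permutation(n)
        mean_a[idx[:160]] = 1.0  # 160 higher in A
        mean_b[idx[160:]] = 1.0  # 190 higher in B
        _res, counts = screen_differential(
            [str(i) for i in range(n)], vip, p, mean_a, mean_b
        )
        assert counts["higher_in_A"] == 160
        assert counts["higher_in_B"] == 190
        assert counts["total_significant"] == 350

    def test_empty_input(self):
        res, counts = screen_differential([], [], [], [], [])
        assert res == [] and counts["total_significant"] == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            screen_differential(["a"], [1.0, 2.0], [0.1], [1.0], [1.0])

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(12)
        n = 200
        ids = [str(i) for i in range(n)]
        vip = rng.uniform(0, 3, n)
        p = rng.uniform(0, 0.2, n)
        ma, mb = rng.normal(size=n), rng.normal(size=n)

        def sig(vip_thr, p_thr):
            res, _ = screen_differential(ids, vip, p, ma, mb,
                                         vip_thr=vip_thr, p_thr=p_thr)
            return {r.feature_id for r in res if r.significant}

        assert sig(1.0, 0.01) <= sig(1.0, 0.05)
        assert sig(1.5, 0.05) <= sig(1.0, 0.05)


class TestShannon:
    def test_closed_forms(self):
        assert shannon_diversity([1, 1, 1, 1]).H == pytest.approx(2.0)
        assert shannon_diversity([0, 7.0, 0]).H == pytest.approx(0.0)
        assert shannon_diversity([0.5, 0.25, 0.25]).H == pytest.approx(1.5)

    def test_bounds_and_uniform_maximum(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            v = rng.uniform(0.1, 10, 16)
            res = shannon_diversity(v)
            assert 0 <= res.H <= np.log2(res.n_nonzero) + 1e-12
        h_max = shannon_diversity(np.ones(16)).H
        for _ in range(10):
            perturbed = np.ones(16) + rng.uniform(0, 1, 16)
            if np.ptp(perturbed) > 0:
                assert shannon_diversity(perturbed).H <= h_max

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            shannon_diversity([0.0, 0.0])


class TestVenn:
    def test_all_positive_matrix_has_no_uniques(self):
        from test_preprocess import make_table

        t = make_table(np.ones((3, 4)), ["a", "b", "c"],
                       ["s1", "s2", "s3", "s4"], ["A", "A", "B", "B"])
        res = venn_counts(t)
        assert res.counts == (0, 0, 3)

    def test_feature_absent_in_b_is_unique_to_a(self):
        from test_preprocess import make_table

        t = make_table([[1, 1, 0, 0], [1, 1, 2, 2]], ["ua", "sh"],
                       ["s1", "s2", "s3", "s4"], ["A", "A", "B", "B"])
        res = venn_counts(t)
        assert res.unique_to_a == ["ua"] and res.shared == ["sh"]

    def test_planted_dropout_counts_recovered(self, seed42_dataset):
        _s, table, truth = seed42_dataset
        res = venn_counts(table)
        assert set(res.unique_to_a) == set(truth.unique_a_ids)
        assert set(res.unique_to_b) == set(truth.unique_b_ids)


class TestPathwayOra:
    def test_matches_exhaustive_enumeration(self):
        """Hypergeometric tail equals brute-force enumeration of all draws
        on a small universe."""
        from itertools import combinations

        background = [f"m{i}" for i in range(8)]
        pathway = set(background[:4])
        diff = set(background[:3])
        df = pathway_ora(diff, background, {"pw": pathway})
        k_obs = len(pathway & diff)
        total = hits = 0
        for draw in combinations(background, len(diff)):
            total += 1
            if len(pathway & set(draw)) >= k_obs:
                hits += 1
        assert df.loc[0, "p_value"] == pytest.approx(hits / total)

    def test_empty_diff_set_gives_p_one(self):
        df = pathway_ora([], ["a", "b", "c"], {"pw": {"a", "b"}})
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_disjoint_pathway_skipped_with_note(self):
        df = pathway_ora(["a"], ["a", "b"], {"pw": {"zzz"}})
        assert np.isnan(df.loc[0, "p_value"])
        assert "background" in df.loc[0, "note"]

    def test_diff_must_be_subset_of_background(self):
        with pytest.raises(ValueError):
            pathway_ora(["x"], ["a"], {"pw": {"a"}})
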