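import numpy as np
import pytest
from scipy import stats

from glandchem.profile_io import ProfileError
from glandchem.rf_stability import (
    RFProtocolConfig,
    chi2_uniform,
    clopper_pearson,
    kappa_from_confusion,
    mean_auc_per_run,
    roc_auc,
    run_protocol,
    stratified_split,
    tune,
)
from glandchem.synthetic import generate

from conftest import small_spec


class TestKappa:
    def test_perfect_agreement(self):
        assert kappa_from_confusion(50, 0, 50, 0) == 1.0

    def test_published_sensitivity_specificity_worked_example(self):
        # class sizes 116 positives / 111 negatives, sensitivity 0.966 and
        # specificity 0.958 -> kappa 0.924 to 3 decimals
        n_pos, n_neg = 116, 111
        tp = 0.966 * n_pos
        fn = n_pos - tp
        tn = 0.958 * n_neg
        fp = n_neg - tn
        assert kappa_from_confusion(tp, fp, tn, fn) == pytest.approx(0.924, abs=5e-4)

    def test_independent_margins_give_zero(self):
        # exact product table: observed == chance agreement
        p1, q1, n = 0.3, 0.6, 1000.0
        tp = p1 * q1 * n
        fp = (1 - p1) * q1 * n
        fn = p1 * (1 - q1) * n
        tn = (1 - p1) * (1 - q1) * n
        assert kappa_from_confusion(tp, fp, tn, fn) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_single_cell_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert kappa_from_confusion(10, 0, 0, 0) == 1.0


class TestChi2Uniform:
    def test_maximal_concentration_closed_form(self):
        # all 1000 runs on one compound out of k = 11 categories:
        # chi2 = n_runs * (k - 1)
        counts = [1000] + [0] * 10
        stat, df, p = chi2_uniform(counts)
        assert stat == pytest.approx(1000 * 10)
        assert df == 10
        assert p < 1e-300

    def test_uniform_counts_give_zero(self):
        stat, df, p = chi2_uniform([100] * 5)
        assert stat == 0.0
        assert p == 1.0

    def test_invariant_to_relabeling(self):
        s1, _, p1 = chi2_uniform([70, 20, 10])
        s2, _, p2 = chi2_uniform([10, 70, 20])
        assert s1 == s2 and p1 == p2


class TestStratifiedSplit:
    def test_study_class_sizes_round_half_up(self):
        labels = np.array(["marthae"] * 116 + ["subcristatus"] * 111)
        train, test = stratified_split(labels, 0.5, 0)
        assert (labels[train] == "marthae").sum() == 58
        assert (labels[train] == "subcristatus").sum() == 56  # 55.5 rounds up
        assert (labels[test] == "marthae").sum() == 58
        assert (labels[test] == "subcristatus").sum() == 55

    def test_disjoint_and_exhaustive(self):
        labels = np.array(["a"] * 9 + ["b"] * 7)
        train, test = stratified_split(labels, 0.6, 3)
        assert set(train).isdisjoint(test)
        assert sorted(np.r_[train, test]) == list(range(16))

    def test_same_seed_same_split(self):
        labels = np.array(["a"] * 10 + ["b"] * 10)
        s1 = stratified_split(labels, 0.5, 99)
        s2 = stratified_split(labels, 0.5, 99)
        np.testing.assert_array_equal(s1[0], s2[0])

    def test_emptied_split_is_error(self):
        labels = np.array(["a", "a", "b", "b"])
        with pytest.raises(ProfileError, match="empties"):
            stratified_split(labels, 0.95, 0)

    def test_singleton_class_is_error(self):
        with pytest.raises(ProfileError, match="fewer than 2"):
            stratified_split(np.array(["a", "b", "b"]), 0.5, 0)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        points, auc = roc_auc(scores, labels)
        assert auc == 1.0
        assert points[0].tolist() == [0.0, 0.0]
        assert points[-1].tolist() == [1.0, 1.0]

    def test_matches_rank_statistic_oracle(self, rng):
        for _ in range(10):
            scores = rng.normal(size=60)
            labels = rng.integers(0, 2, size=60)
            if labels.sum() in (0, 60):
                continue
            _, auc = roc_auc(scores, labels)
            u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                                   alternative="two-sided").statistic
            n1, n0 = (labels == 1).sum(), (labels == 0).sum()
            assert auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_uninformative_scores_near_half(self, rng):
        n = 4000
        scores = rng.random(n)
        labels = rng.integers(0, 2, size=n)
        _, auc = roc_auc(scores, labels)
        n1, n0 = (labels == 1).sum(), (labels == 0).sum()
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(auc - 0.5) < 3 * se

    def test_ties_share_threshold(self):
        scores = [0.5, 0.5, 0.5, 0.5]
        labels = [1, 0, 1, 0]
        points, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5)
        assert len(points) == 2  # (0,0) and (1,1) only

    def test_single_class_is_error(self):
        with pytest.raises(ProfileError):
            roc_auc([0.1, 0.9], [1, 1])


class TestClopperPearson:
    def test_bounds_bracket_point_estimate(self):
        low, high = clopper_pearson(90, 100)
        assert low < 0.9 < high

    def test_extremes(self):
        assert clopper_pearson(0, 20)[0] == 0.0
        assert clopper_pearson(20, 20)[1] == 1.0


class TestTune:
    def test_single_point_grid(self):
        table, meta = generate(small_spec(1, n_per_group=15, delta_species=3.0))
        assert tune(table, meta["species"].to_numpy(), [(50, 3)], seed=0) == (50, 3)

    def test_mtry_exceeding_compounds_is_error(self):
        table, meta = generate(small_spec(1, n_per_group=10))
        with pytest.raises(ProfileError, match="mtry"):
            tune(table, meta["species"].to_numpy(), [(50, 999)], seed=0)

    def test_separable_data_low_oob_everywhere_and_deterministic(self):
        table, meta = generate(small_spec(2, n_per_group=25, delta_species=4.0))
        grid = [(100, 3), (100, 6)]
        pick1 = tune(table, meta["species"].to_numpy(), grid, seed=5)
        pick2 = tune(table, meta["species"].to_numpy(), grid, seed=5)
        assert pick1 == pick2
        assert pick1 in grid


class TestProtocol:
    @pytest.fixture(scope="class")
    def planted(self):
        spec = small_spec(8, n_per_group=30, n_compounds=12, delta_species=4.0)
        return generate(spec)

    def test_counts_and_metrics_consistent(self, planted):
        table, meta = planted
        cfg = RFProtocolConfig(n_runs=8, n_trees=60, mtry=4, master_seed=1)
        res = run_protocol(table, meta["species"].to_numpy(), cfg)
        assert sum(res.frequency.values()) == 8
        for r in res.runs:
            assert r.tp + r.fp + r.tn + r.fn == len(r.scores)
            assert r.ci_low <= r.accuracy <= r.ci_high
        # averaged accuracy is the mean of per-run accuracies, not pooled
        assert res.mean_metrics["accuracy"] == pytest.approx(
            np.mean([r.accuracy for r in res.runs])
        )
        assert 0.0 <= res.auc <= 1.0
        assert mean_auc_per_run(res) <= 1.0

    def test_bit_reproducible_for_fixed_master_seed(self, planted):
        table, meta = planted
        cfg = RFProtocolConfig(n_runs=4, n_trees=40, mtry=4, master_seed=77)
        r1 = run_protocol(table, meta["species"].to_numpy(), cfg)
        r2 = run_protocol(table, meta["species"].to_numpy(), cfg)
        assert r1.frequency == r2.frequency
        assert r1.mean_metrics == r2.mean_metrics
        assert r1.auc == r2.auc

    def test_strong_markers_dominate_tally(self, planted):
        table, meta = planted
        cfg = RFProtocolConfig(n_runs=10, n_trees=60, mtry=4, master_seed=3)
        res = run_protocol(table, meta["species"].to_numpy(), cfg)
        planted_ids = {"c001", "c002", "c003"}
        on_planted = sum(v for k, v in res.frequency.items() if k in planted_ids)
        assert on_planted >= 9
        assert res.mean_metrics["sensitivity"] > 0.9
        assert res.mean_metrics["specificity"] > 0.9

    def test_non_binary_labels_rejected(self, planted):
        table, _ = planted
        labels = np.array(["a"] * table.n_samples)
        with pytest.raises(ProfileError, match="binary"):
            run_protocol(table, labels, RFProtocolConfig(n_runs=1))
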