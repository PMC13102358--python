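import numpy as np
import pytest
from scipy.special import gammaln

from introscan.evaluation import (
    ConfusionTable,
    evaluate_thresholds,
    joint_sfs,
    ll_multinom,
    mask_corners,
    opposite_frequency_mass,
    precision_recall,
)

EL, IL, BI, NONE = range(4)


class TestPrecisionRecall:
    def test_diagonal_perfect(self):
        table = ConfusionTable(np.eye(4, dtype=int) * 10)
        rep = precision_recall(table)
        assert all(v == 1.0 for v in rep.precision.values())
        assert all(v == 1.0 for v in rep.recall.values())

    def test_counting_example(self):
        # true ELtoIL 10: predicted 8 ELtoIL + 2 none; true none 10: all none
        counts = np.zeros((4, 4), dtype=int)
        counts[EL, EL] = 8
        counts[EL, NONE] = 2
        counts[NONE, NONE] = 10
        rep = precision_recall(ConfusionTable(counts))
        assert rep.precision["ELtoIL"] == 1.0
        assert rep.recall["ELtoIL"] == 0.8

    def test_never_predicted_class(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[IL, NONE] = 5
        counts[NONE, NONE] = 5
        rep = precision_recall(ConfusionTable(counts))
        assert rep.precision["ILtoEL"] is None
        assert rep.recall["ILtoEL"] == 0.0

    def test_directionality_restricted_to_detected(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[EL, EL] = 6
        counts[EL, IL] = 2
        counts[EL, NONE] = 92  # presence misses do not enter directionality
        counts[IL, IL] = 4
        rep = precision_recall(ConfusionTable(counts))
        assert rep.directionality_precision["ELtoIL"] == 1.0
        assert rep.directionality_precision["ILtoEL"] == pytest.approx(4 / 6)
        assert rep.directionality_recall["ELtoIL"] == pytest.approx(6 / 8)

    def test_presence_binary_collapse(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[EL, BI] = 3  # wrong direction, correct presence
        counts[NONE, EL] = 1
        counts[NONE, NONE] = 6
        rep = precision_recall(ConfusionTable(counts))
        assert rep.presence_precision == pytest.approx(3 / 4)
        assert rep.presence_recall == 1.0

    def test_row_sums_invariant(self, rng):
        counts = rng.integers(0, 20, (4, 4))
        table = ConfusionTable(counts)
        assert (table.counts.sum(axis=1) == counts.sum(axis=1)).all()


class TestEvaluateThresholds:
    def _probs_labels(self):
        probs = np.array(
            [
                [0.95, 0.01, 0.02, 0.02],
                [0.01, 0.80, 0.05, 0.14],
                [0.05, 0.05, 0.85, 0.05],
                [0.10, 0.10, 0.10, 0.70],
            ]
        )
        labels = np.array([EL, IL, BI, NONE])
        return probs, labels

    def test_five_rows(self):
        probs, labels = self._probs_labels()
        reports = evaluate_thresholds(probs, labels)
        assert len(reports) == 5
        assert set(reports) == {0.75, 0.8, 0.85, 0.9, 0.95}

    def test_p_one_no_positive_calls(self):
        probs, labels = self._probs_labels()
        rep = evaluate_thresholds(probs, labels, thresholds=[1.0])[1.0]
        assert rep.presence_recall == 0.0
        assert rep.presence_precision is None

    def test_recall_monotone_down_in_p(self):
        probs, labels = self._probs_labels()
        reports = evaluate_thresholds(probs, labels)
        recalls = [reports[p].presence_recall for p in sorted(reports)]
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))


class TestJointSfs:
    def test_single_site_cell(self):
        m = np.zeros((8, 1), dtype=np.int8)
        m[:3, 0] = 1  # count (3, 0) in samples (4, 4)
        sfs = joint_sfs(m, 4, fold_minor=False)
        assert sfs[3, 0] == 1
        assert sfs.sum() == 1

    def test_total_is_site_count(self, rng):
        m = rng.integers(0, 2, (10, 57))
        assert joint_sfs(m, 6).sum() == 57

    def test_monomorphic_mass_in_corner(self):
        m = np.zeros((6, 5), dtype=np.int8)
        sfs = joint_sfs(m, 3)
        assert sfs[0, 0] == 5

    def test_fold_minor_bounds(self, rng):
        m = rng.integers(0, 2, (9, 40))
        sfs = joint_sfs(m, 5)
        total_counts = np.add.outer(np.arange(6), np.arange(5))
        assert sfs[total_counts > 9 / 2].sum() == 0


class TestLlMultinom:
    def test_self_likelihood_optimal(self, rng):
        data = rng.integers(0, 20, (5, 5)).astype(float)
        ll_self = ll_multinom(data, data)
        other = rng.integers(1, 20, (5, 5)).astype(float)
        other *= data.sum() / other.sum()
        assert ll_multinom(data, other) <= ll_self + 1e-9

    def test_scaling_invariance(self, rng):
        data = rng.integers(0, 15, (4, 6)).astype(float)
        model = rng.integers(1, 15, (4, 6)).astype(float)
        assert ll_multinom(data, model) == pytest.approx(
            ll_multinom(data, 7.3 * model)
        )

    def test_brute_force_small_example(self):
        data = np.array([[0.0, 2.0], [1.0, 0.0]])
        model = np.array([[0.0, 1.0], [1.0, 0.0]])
        mask = np.ones((2, 2), dtype=bool)
        mask[0, 0] = False
        mask[1, 1] = False
        theta = 3.0 / 2.0
        expected = 0.0
        for d, m in [(2.0, 1.0), (1.0, 1.0)]:
            expected += d * np.log(theta * m) - theta * m - gammaln(d + 1)
        assert ll_multinom(data, model, mask=mask) == pytest.approx(float(expected))

    def test_model_zero_where_data_positive(self):
        data = np.array([[0.0, 1.0], [0.0, 0.0]])
        model = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning):
            assert ll_multinom(data, model) == float("-inf")

    def test_corner_mask(self):
        mask = mask_corners(np.zeros((3, 4)))
        assert not mask[0, 0] and not mask[2, 3]
        assert mask.sum() == 10


def test_sfs_text_round_trip(tmp_path, rng):
    from introscan.evaluation import load_sfs, save_sfs

    m = rng.integers(0, 2, (10, 30))
    sfs = joint_sfs(m, 6)
    path = tmp_path / "sfs.txt"
    save_sfs(path, sfs)
    restored, meta = load_sfs(path)
    assert np.array_equal(restored, sfs)
    assert (meta["n1"], meta["n2"]) == (6, 4)


def test_opposite_frequency_mass_zero_on_empty():
    assert opposite_frequency_mass(np.zeros((5, 5), dtype=int)) == 0.0


class TestEvaluationSets:
    FAST = dict(region_bp=2e4, window_snps=16, mutation_scale=15.0)

    def test_depth_sweep_sizes_and_ordering(self, model_w1):
        from introscan.evaluation import build_depth_sweep_sets

        rng = np.random.default_rng(8)
        sets = build_depth_sweep_sets(
            model_w1, 3, (4, 3), rng, depths=(2, 6), **self.FAST
        )
        assert set(sets) == {2, 6}
        for lam, (x, y) in sets.items():
            assert len(y) == 3 * 4
            assert x.shape[1:] == (2, 8, 16)

    def test_depth_corruption_decreases_with_depth(self, model_w1):
        # same simulations, different depth: lambda = 6 alters fewer genotypes
        from introscan.evaluation import _corrupt_example
        from introscan.scenario_simulator import (
            DepthErrorConfig,
            ScenarioSpec,
            simulate_example,
        )

        rng = np.random.default_rng(9)
        ex = simulate_example(model_w1, ScenarioSpec("none"), (6, 4), rng, **self.FAST)
        changes = {}
        for lam in (2.0, 6.0):
            out = _corrupt_example(
                ex, DepthErrorConfig(mean_depth=lam), np.random.default_rng(1), None, None
            )
            changes[lam] = (out.alignment.matrix != ex.alignment.matrix).sum()
        assert changes[6.0] < changes[2.0]

    def test_realistic_set_reduces_to_ideal(self, model_w1):
        from introscan.evaluation import build_evaluation_set, build_realistic_set

        ideal = build_evaluation_set(
            model_w1, 2, (4, 3), np.random.default_rng(4), **self.FAST
        )
        realistic = build_realistic_set(
            model_w1, 2, (4, 3), (0, 0), np.random.default_rng(4),
            heterogeneity=None, **self.FAST
        )
        np.testing.assert_array_equal(ideal[0], realistic[0])

    def test_realistic_low_depth_counts_validated(self, model_w1):
        from introscan.evaluation import build_realistic_set

        with pytest.raises(ValueError, match="exceed"):
            build_realistic_set(
                model_w1, 1, (4, 3), (5, 1), np.random.default_rng(0), **self.FAST
            )
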