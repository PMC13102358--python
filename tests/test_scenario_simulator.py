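import math

import numpy as np
import pytest

from introscan import CLASS_LABELS
from introscan.scenario_simulator import (
    DepthErrorConfig,
    RateHeterogeneityConfig,
    ScenarioSpec,
    build_training_set,
    draw_scenario,
    inject_depth_errors,
    load_training_set,
    sample_rate_scaler,
    simulate_example,
)

FAST_SIM = dict(region_bp=3e4, window_snps=32, mutation_scale=10.0)


class TestScenarioSpec:
    def test_none_forbids_pulses(self):
        with pytest.raises(ValueError):
            ScenarioSpec(label="none", pulses={"ELtoIL": (0.2, 100)})

    def test_bidir_needs_both(self):
        with pytest.raises(ValueError):
            ScenarioSpec(label="BiDir", pulses={"ELtoIL": (0.2, 100)})

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            ScenarioSpec(label="ELtoIL", pulses={"ELtoIL": (0.6, 100)})
        with pytest.raises(ValueError):
            ScenarioSpec(label="ELtoIL", pulses={"ELtoIL": (0.2, 6000)})


class TestDrawScenario:
    def test_bounds_many_draws(self, rng):
        for _ in range(2000):
            spec = draw_scenario("ELtoIL", rng)
            prop, t = spec.pulses["ELtoIL"]
            assert 0.05 <= prop <= 0.50
            assert 1 <= t <= 5000

    def test_none_has_no_pulses(self, rng):
        assert draw_scenario("none", rng).pulses == {}

    def test_mean_proportion(self, rng):
        props = [draw_scenario("ELtoIL", rng).pulses["ELtoIL"][0] for _ in range(20_000)]
        # mean of Uniform(0.05, 0.50) = 0.275; MC standard error
        se = (0.50 - 0.05) / np.sqrt(12 * len(props))
        assert abs(np.mean(props) - 0.275) < 4 * se

    def test_bidir_independent_directions(self, rng):
        a = np.array([list(draw_scenario("BiDir", rng).pulses["ELtoIL"]) for _ in range(3000)])
        b = np.array([list(draw_scenario("BiDir", rng).pulses["ILtoEL"]) for _ in range(3000)])
        assert abs(np.corrcoef(a[:, 0], b[:, 0])[0, 1]) < 0.08


class TestRateScaler:
    def test_moments(self, rng):
        cfg = RateHeterogeneityConfig()
        draws = np.array([sample_rate_scaler(cfg, rng) for _ in range(100_000)])
        # mean 1 within 3 SE; variance = shape * scale^2 = 0.1
        se = np.sqrt(0.1 / len(draws))
        assert abs(draws.mean() - 1.0) < 3 * se
        assert draws.var() == pytest.approx(0.1, rel=0.05)
        assert (draws > 0).all()

    def test_scale_defaults_to_inverse_shape(self):
        assert RateHeterogeneityConfig(shape=10).scale == pytest.approx(0.1)

    def test_invalid_shape(self):
        with pytest.raises(ValueError):
            RateHeterogeneityConfig(shape=0)


class TestInjectDepthErrors:
    def _het_matrix(self, n_sites, rng):
        a = rng.integers(0, 2, n_sites)
        m = np.stack([a, 1 - a])  # one individual, all het
        return m.astype(np.int8)

    def test_depth_one_always_homozygous(self, rng):
        m = self._het_matrix(500, rng)
        # mean so small that max(1, Poisson) is almost surely 1
        out = inject_depth_errors(m, DepthErrorConfig(mean_depth=1e-9), rng)
        assert (out[0] == out[1]).all()

    def test_homozygous_never_altered(self, rng):
        m = np.repeat(rng.integers(0, 2, (1, 300)), 2, axis=0).astype(np.int8)
        out = inject_depth_errors(m, DepthErrorConfig(mean_depth=2.0), rng)
        assert np.array_equal(out, m)

    def test_miscall_rate_matches_expectation(self, rng):
        # oracle: E[2 * (1/2)^d], d = max(1, Poisson(lam)), truncated sum
        lam = 4.0
        n = 100_000
        m = self._het_matrix(n, rng)
        out = inject_depth_errors(m, DepthErrorConfig(mean_depth=lam), rng)
        miscall = (out[0] == out[1]).mean()
        expected = sum(
            (math.exp(-lam) * lam**k / math.factorial(k)) * 2.0 * 0.5 ** max(1, k)
            for k in range(0, 60)
        )
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(miscall - expected) < 3 * se

    def test_large_depth_limit_no_changes(self, rng):
        m = self._het_matrix(2000, rng)
        out = inject_depth_errors(m, DepthErrorConfig(mean_depth=200.0), rng)
        assert np.array_equal(out, m)

    def test_only_designated_individuals(self, rng):
        a = rng.integers(0, 2, 400)
        m = np.stack([a, 1 - a, a, 1 - a]).astype(np.int8)  # two het individuals
        out = inject_depth_errors(m, DepthErrorConfig(mean_depth=1e-9), rng, individuals=[1])
        assert np.array_equal(out[:2], m[:2])
        assert (out[2] == out[3]).all()

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            DepthErrorConfig(mean_depth=0)


class TestSimulateExample:
    def test_none_has_no_flags(self, model_w1, rng):
        ex = simulate_example(model_w1, ScenarioSpec("none"), (6, 4), rng, **FAST_SIM)
        assert not ex.introgressed.any()
        assert ex.alignment.n_sites >= 32

    def test_eltoil_flags_recipient_side(self, model_w1, rng):
        ex = simulate_example(model_w1, draw_scenario("ELtoIL", rng), (6, 4), rng, **FAST_SIM)
        assert ex.introgressed[:12].any()  # IL haplotypes
        assert not ex.introgressed[12:].any()

    def test_bidir_flags_both_sides(self, model_w1, rng):
        ex = simulate_example(model_w1, draw_scenario("BiDir", rng), (6, 4), rng, **FAST_SIM)
        assert ex.introgressed[:12].any()
        assert ex.introgressed[12:].any()

    def test_positions_strictly_increasing(self, model_w1, rng):
        ex = simulate_example(model_w1, ScenarioSpec("none"), (6, 4), rng, **FAST_SIM)
        assert (np.diff(ex.alignment.positions) > 0).all()

    def test_exhausted_attempts_raise_with_spec(self, model_w1, rng):
        spec = draw_scenario("ELtoIL", rng)
        with pytest.raises(RuntimeError, match="ELtoIL"):
            simulate_example(
                model_w1, spec, (6, 4), rng, region_bp=1e3,
                window_snps=5000, mutation_scale=1.0, max_attempts=2,
            )

    def test_pulse_effect_monotone_in_proportion(self, model_w1):
        # mean flagged recipient haplotypes at proportion 0.5 strictly exceeds 0.05
        def mean_flagged(prop, seed):
            rng = np.random.default_rng(seed)
            total = 0
            n = 60
            for _ in range(n):
                spec = ScenarioSpec("ELtoIL", {"ELtoIL": (prop, 500.0)})
                ex = simulate_example(model_w1, spec, (6, 4), rng, **FAST_SIM)
                total += ex.introgressed[:12].sum()
            return total / n

        assert mean_flagged(0.5, 11) > mean_flagged(0.05, 11)


class TestBuildTrainingSet:
    def test_manifest_accounting_tiny(self, model_w1, tmp_path):
        manifest = build_training_set(
            [model_w1], 10, (4, 3), tmp_path, seed=5, **FAST_SIM
        )
        assert manifest["total"] == 40
        x, y, midx, val, m2 = load_training_set(tmp_path)
        assert len(x) == 40
        assert m2["total"] == 40
        # uniform label proportions by construction
        assert [int((y == c).sum()) for c in range(4)] == [10, 10, 10, 10]
        # stratified validation: ceil(0.05 * 10) = 1 per (model, label)
        for c in range(4):
            assert val[y == c].sum() == 1

    def test_tensor_shape_and_binary(self, model_w1, tmp_path):
        build_training_set([model_w1], 2, (4, 3), tmp_path, seed=1, **FAST_SIM)
        x, y, _, _, manifest = load_training_set(tmp_path)
        assert x.shape[1:] == (2, 8, 32)
        assert set(np.unique(x)) <= {0, 1}
        assert manifest["class_labels"] == list(CLASS_LABELS)

    def test_total_formula_two_models(self, model_w1, tiny_model, tmp_path):
        manifest = build_training_set(
            [model_w1, tiny_model], 3, (3, 3), tmp_path, seed=2, **FAST_SIM
        )
        assert manifest["total"] == 3 * 4 * 2

    def test_invalid_count(self, model_w1, tmp_path):
        with pytest.raises(ValueError):
            build_training_set([model_w1], 0, (4, 3), tmp_path)


class TestSfsContrast:
    def test_none_has_less_opposite_frequency_sharing(self, model_w1):
        from introscan.evaluation import joint_sfs, opposite_frequency_mass

        rng = np.random.default_rng(17)
        mass = {}
        for label in ("none", "ELtoIL"):
            sfs_total = np.zeros((13, 9), dtype=np.int64)
            for _ in range(40):
                spec = draw_scenario(label, rng) if label != "none" else ScenarioSpec("none")
                ex = simulate_example(model_w1, spec, (6, 4), rng, **FAST_SIM)
                sfs_total += joint_sfs(ex.alignment.matrix, 12)
            mass[label] = opposite_frequency_mass(sfs_total, border=2)
        assert mass["none"] < mass["ELtoIL"]
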