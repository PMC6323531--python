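import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import foadpc as f
from foadpc import foa_opt
from foadpc.foa_opt import ConfigError, FOAConfig, decode, select_best


def quadratic(params):
    return -((params.d_c - 5.0) ** 2 + (params.k - 20.0) ** 2)


class TestConfig:
    def test_defaults_match_reference_setup(self):
        cfg = FOAConfig()
        assert (cfg.sizepop, cfg.maxgen) == (10, 10)
        assert (cfg.step_low, cfg.step_high) == (-5.0, 5.0)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(sizepop=0), dict(maxgen=0), dict(step_low=5, step_high=-5),
         dict(step_low=0, step_high=0), dict(bounds=((5, 5), (2, 40)))],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            FOAConfig(**kwargs)


class TestClassicTransform:
    def test_three_four_five(self):
        assert foa_opt.smell_concentration(3.0, 4.0) == (5.0, pytest.approx(0.2))

    def test_origin_degenerate(self):
        dist, s = foa_opt.smell_concentration(0.0, 0.0)
        assert dist == 0.0 and s == np.inf


class TestDecode:
    def test_clamps_low(self):
        p = decode(np.array([0.2, 1.1]))
        assert p.d_c == 1.0 and p.k == 2

    def test_rounds_half_up(self):
        assert decode(np.array([5.0, 12.7])).k == 13
        assert decode(np.array([5.0, 12.5])).k == 13
        assert decode(np.array([5.0, 12.49])).k == 12

    def test_clamps_high(self):
        p = decode(np.array([99.0, 99.0]))
        assert p.d_c == 10.0 and p.k == 40

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            decode(np.array([np.nan, 5.0]))

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6))
    def test_always_within_bounds(self, x, y):
        p = decode(np.array([x, y]))
        assert 1.0 <= p.d_c <= 10.0 and 2 <= p.k <= 40


class TestSwarmSteps:
    def test_proposals_within_step_of_anchor(self):
        rng = np.random.default_rng(3)
        cfg = FOAConfig(seed=3)
        swarm = foa_opt.init_swarm(cfg, rng)
        pos = foa_opt.smell_step(swarm, cfg, rng)
        assert pos.shape == (10, 2)
        assert np.all(np.abs(pos - swarm.axis) <= 5.0)

    def test_seeded_reproducibility(self):
        def run():
            rng = np.random.default_rng(11)
            swarm = foa_opt.init_swarm(FOAConfig(seed=11), rng)
            return swarm.axis, foa_opt.smell_step(swarm, FOAConfig(seed=11), rng)
        (a1, p1), (a2, p2) = run(), run()
        assert np.array_equal(a1, a2) and np.array_equal(p1, p2)


class TestSelectBest:
    def test_argmax(self):
        assert select_best([4.1, 4.7, 4.3]) == (4.7, 1)

    def test_tie_goes_to_first(self):
        assert select_best([4.7, 4.7]) == (4.7, 0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_best([])

    def test_nonfinite_errors(self):
        with pytest.raises(ValueError):
            select_best([1.0, np.nan])


class TestOptimize:
    def test_fixed_seed_bit_identical(self):
        r1 = foa_opt.optimize(quadratic, FOAConfig(seed=5))
        r2 = foa_opt.optimize(quadratic, FOAConfig(seed=5))
        assert r1.best_params == r2.best_params
        assert r1.best_smell == r2.best_smell
        assert np.array_equal(r1.trace, r2.trace)

    def test_trace_nondecreasing_and_counts(self):
        calls = []

        def counted(params):
            calls.append(params)
            return quadratic(params)

        res = foa_opt.optimize(counted, FOAConfig(seed=2, maxgen=7))
        assert len(calls) == 70 and res.evaluations == 70
        assert len(res.trace) == 7
        assert np.all(np.diff(res.trace) >= 0)

    def test_maxgen_one_evaluates_one_generation(self):
        calls = []
        foa_opt.optimize(lambda p: calls.append(p) or 0.0,
                         FOAConfig(seed=1, maxgen=1))
        assert len(calls) == 10

    def test_constant_fitness_flat_trace(self):
        res = foa_opt.optimize(lambda p: 1.5, FOAConfig(seed=4))
        assert np.all(res.trace == 1.5)
        assert res.best_params is not None

    def test_sizepop_one_still_runs(self):
        res = foa_opt.optimize(quadratic, FOAConfig(sizepop=1, seed=0))
        assert res.evaluations == 10

    def test_nonfinite_fitness_raises(self):
        with pytest.raises(ValueError):
            foa_opt.optimize(lambda p: float("nan"), FOAConfig(seed=0))

    def test_quadratic_recovers_optimum(self):
        # smooth test objective peaked at (d_c, k) = (5, 20)
        hits = 0
        for seed in range(20):
            res = foa_opt.optimize(quadratic,
                                   FOAConfig(seed=seed, maxgen=30))
            d = np.hypot(res.best_params.d_c - 5.0, res.best_params.k - 20.0)
            hits += d <= 1.0
        assert hits >= 18

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_decoded_params_always_valid(self, seed):
        seen = []

        def spy(params):
            seen.append(params)
            return 0.0

        foa_opt.optimize(spy, FOAConfig(seed=seed, maxgen=3))
        for p in seen:
            assert 1.0 <= p.d_c <= 10.0 and 2 <= p.k <= 40
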