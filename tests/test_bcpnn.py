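"""Core BCPNN machinery: normalization, traces, weights, support, stepping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tristage.bcpnn import (
    INF,
    FixedProjection,
    Population,
    PopulationParams,
    Projection,
    TraceState,
    compute_bias,
    compute_support,
    compute_weights,
    normalize_kwta,
    normalize_softmax,
    step_population,
    update_traces,
)
from tristage.layout import HypercolumnLayout


def small_population(n_hc=2, size=2, tau_C=1.0):
    return Population(
        HypercolumnLayout.uniform(n_hc, size), PopulationParams(tau_C=tau_C)
    )


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------


class TestLayout:
    def test_sizes_must_sum_to_n_units(self):
        with pytest.raises(ValueError):
            HypercolumnLayout(10, (5, 4))

    def test_membership_assigns_each_unit_once(self):
        lay = HypercolumnLayout(7, (3, 4))
        assert list(lay.membership) == [0, 0, 0, 1, 1, 1, 1]
        assert [len(range(s.start, s.stop)) for s in lay.slices()] == [3, 4]

    def test_non_modular_is_single_group(self):
        lay = HypercolumnLayout.flat(250)
        assert lay.n_hypercolumns == 1 and not lay.modular
        with pytest.raises(ValueError):
            HypercolumnLayout(10, (5, 5), modular=False)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


class TestSoftmax:
    def test_equal_supports_give_uniform_activity(self):
        lay = HypercolumnLayout.uniform(1, 10)
        act = normalize_softmax(np.full(10, 3.7), lay)
        assert np.allclose(act, 0.1)

    def test_dominant_support_saturates(self):
        lay = HypercolumnLayout.uniform(1, 10)
        s = np.zeros(10)
        s[4] = 60.0
        act = normalize_softmax(s, lay)
        assert act[4] >= 1 - 1e-12 and np.all(act[np.arange(10) != 4] < 1e-20)

    def test_two_unit_closed_form(self):
        lay = HypercolumnLayout.uniform(1, 2)
        act = normalize_softmax(np.array([1.0, 0.0]), lay)
        e = math.e
        assert np.allclose(act, [e / (e + 1), 1 / (e + 1)], atol=1e-15)

    def test_stable_under_large_supports(self):
        lay = HypercolumnLayout.uniform(2, 5)
        act = normalize_softmax(np.full(10, 5000.0), lay)
        assert np.all(np.isfinite(act)) and np.allclose(act, 0.2)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=20, max_size=20))
    def test_sums_to_one_per_hypercolumn(self, vals):
        lay = HypercolumnLayout.uniform(4, 5)
        act = normalize_softmax(np.array(vals), lay)
        sums = act.reshape(4, 5).sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestKwta:
    def test_top_k_of_decreasing_supports(self):
        support = -np.arange(250, dtype=float)
        act = normalize_kwta(support, 13)
        assert act[:13].sum() == 13 and act[13:].sum() == 0

    def test_ties_broken_toward_lowest_index(self):
        act = normalize_kwta(np.zeros(250), 13)
        assert np.array_equal(np.flatnonzero(act), np.arange(13))

    def test_k_equal_n_activates_all(self):
        assert normalize_kwta(np.random.default_rng(0).normal(size=8), 8).sum() == 8

    def test_rejects_bad_k(self):
        with pytest.raises(ValueError):
            normalize_kwta(np.zeros(5), 0)
        with pytest.raises(ValueError):
            normalize_kwta(np.zeros(5), 6)

    def test_dead_units_never_win(self):
        alive = np.ones(10, dtype=bool)
        alive[:5] = False
        act = normalize_kwta(np.arange(10, 0, -1, dtype=float), 3, alive=alive)
        assert np.array_equal(np.flatnonzero(act), [5, 6, 7])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 20), st.integers(0, 2**31 - 1))
    def test_exactly_k_winners(self, k, seed):
        support = np.random.default_rng(seed).normal(size=20)
        assert normalize_kwta(support, k).sum() == k


# ---------------------------------------------------------------------------
# traces and the learning rule
# ---------------------------------------------------------------------------


def make_traces(pre, post=None, pair=None, floor=0.0):
    pre = np.asarray(pre, dtype=float)
    post = pre if post is None else np.asarray(post, dtype=float)
    if pair is None:
        pair = np.multiply.outer(pre, post)
    return TraceState(pre, post, np.asarray(pair, dtype=float), floor, floor)


class TestTraceUpdate:
    def test_fixed_point_leaves_traces_unchanged(self):
        tr = make_traces([0.3, 0.7])
        before = tr.pair_rates.copy()
        update_traces(tr, np.array([0.3, 0.7]), np.array([0.3, 0.7]), tau=50.0, dt=10.0)
        assert np.allclose(tr.pre_rates, [0.3, 0.7], atol=1e-15)
        assert np.allclose(tr.pair_rates, before, atol=1e-15)

    @pytest.mark.parametrize("tau", [8.0, 120.0, 18500.0])
    def test_matches_continuous_exponential_closed_form(self, tau):
        """Constant input: Lambda(t) = pi + (Lambda0 - pi) exp(-t/tau)."""
        lam0, target, dt, n = 0.25, 0.9, 10.0, 40
        tr = make_traces([lam0])
        act = np.array([target])
        for _ in range(n):
            update_traces(tr, act, act, tau=tau, dt=dt)
        expected = target + (lam0 - target) * math.exp(-n * dt / tau)
        assert abs(tr.pre_rates[0] - expected) < 1e-12

    def test_frozen_tau_is_identity(self):
        tr = make_traces([0.2, 0.8])
        before = (tr.pre_rates.copy(), tr.pair_rates.copy())
        update_traces(tr, np.array([1.0, 0.0]), np.array([1.0, 0.0]), tau=INF, dt=10.0)
        assert np.array_equal(tr.pre_rates, before[0])
        assert np.array_equal(tr.pair_rates, before[1])

    def test_rate_multiplier_scales_the_rate(self):
        tr1 = make_traces([0.1])
        tr2 = make_traces([0.1])
        act = np.array([1.0])
        update_traces(tr1, act, act, tau=200.0, dt=10.0, rate_multiplier=2.0)
        update_traces(tr2, act, act, tau=100.0, dt=10.0)
        assert np.allclose(tr1.pre_rates, tr2.pre_rates, atol=1e-15)

    def test_rejects_non_positive_tau(self):
        tr = make_traces([0.5])
        with pytest.raises(ValueError):
            update_traces(tr, np.array([1.0]), np.array([1.0]), tau=-5.0, dt=10.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.floats(11.0, 1000.0))
    def test_rates_stay_in_unit_interval(self, seed, tau):
        rng = np.random.default_rng(seed)
        tr = make_traces(rng.uniform(0, 1, 4))
        for _ in range(20):
            act = rng.uniform(0, 1, 4)
            update_traces(tr, act, act, tau=tau, dt=10.0)
        assert np.all(tr.pre_rates >= 0) and np.all(tr.pre_rates <= 1)
        assert np.all(tr.pair_rates >= 0) and np.all(tr.pair_rates <= 1)

    def test_symmetry_preserved_under_symmetric_updates(self):
        rng = np.random.default_rng(3)
        tr = make_traces(rng.uniform(0.1, 0.9, 6))
        for _ in range(50):
            act = rng.uniform(0, 1, 6)
            update_traces(tr, act, act, tau=40.0, dt=10.0)
        assert np.max(np.abs(tr.pair_rates - tr.pair_rates.T)) < 1e-9


class TestBiasAndWeights:
    def test_bias_of_unit_rate_one_is_zero(self):
        assert compute_bias(make_traces([1.0]))[0] == 0.0

    def test_bias_is_log_of_rate(self):
        assert abs(compute_bias(make_traces([0.1]))[0] - math.log(0.1)) < 1e-12

    def test_uniform_rates_give_equal_biases(self):
        b = compute_bias(make_traces(np.full(10, 0.1)))
        assert np.allclose(b, -math.log(10))

    def test_bias_rejects_zero_rate(self):
        with pytest.raises(ValueError):
            compute_bias(make_traces([0.0, 0.5]))

    def test_independent_units_give_unit_weight_in_small_lambda_limit(self):
        tr = make_traces([0.3, 0.6])  # pair = outer product: independence
        w = compute_weights(tr, lambda_0=1e-9)
        assert np.allclose(w, 1.0, atol=1e-6)

    def test_matches_scalar_arithmetic_oracle(self):
        lam = 0.025
        li, lj, lij = 0.1, 0.1, 0.1
        tr = make_traces([li], [lj], [[lij]])
        # independent scalar evaluation of the weight formula
        num = (1 - lam**2) * lij + lam**2
        den = ((1 - lam) * li + lam) * ((1 - lam) * lj + lam)
        assert abs(compute_weights(tr, lam)[0, 0] - num / den) < 1e-14

    def test_boundary_cases(self):
        lam = 0.025
        # both rates and the pair at zero: fully uninformative -> weight one
        assert abs(compute_weights(make_traces([0.0], [0.0], [[0.0]]), lam)[0, 0] - 1.0) < 1e-12
        # perfect anticorrelation: the minimum weight lambda_0^2
        w = compute_weights(make_traces([1.0], [1.0], [[0.0]]), lam)[0, 0]
        assert abs(w - lam**2) < 1e-12
        assert w > 0

    def test_weights_strictly_positive_for_random_traces(self):
        rng = np.random.default_rng(11)
        tr = make_traces(rng.uniform(0, 1, 5), rng.uniform(0, 1, 5), rng.uniform(0, 1, (5, 5)))
        assert np.all(compute_weights(tr, 0.025) > 0)

    def test_rejects_bad_lambda(self):
        with pytest.raises(ValueError):
            compute_weights(make_traces([0.5]), 0.0)


# ---------------------------------------------------------------------------
# support and stepping
# ---------------------------------------------------------------------------


class TestSupport:
    def test_zero_gains_relax_support_to_zero(self):
        pop = small_population()
        pop.support = np.array([5.0, -3.0, 2.0, 1.0])
        for _ in range(3):
            pop.support = compute_support(pop, [], dt=10.0)
        assert np.all(np.abs(pop.support) < 1e-9)

    def test_unit_weights_reduce_support_to_bias(self):
        pop = small_population(n_hc=2, size=5)
        proj = Projection(pop, pop, tau=INF, gain=1.0, lambda_0=1e-12)
        # uniform independent traces -> weights 1 up to O(lambda_0);
        # iterate the (effectively instantaneous) relaxation to its target
        for _ in range(4):
            pop.support = compute_support(pop, [proj], dt=10.0)
        assert np.allclose(pop.support, proj.bias, atol=1e-6)

    def test_matches_term_by_term_oracle(self):
        """Hand-set traces on a 2-hypercolumn toy against an explicit loop."""
        rng = np.random.default_rng(5)
        pop = small_population(n_hc=2, size=2)
        proj = Projection(pop, pop, tau=INF, gain=1.0)
        tr = proj.traces
        tr.pre_rates[:] = rng.uniform(0.1, 0.9, 4)
        tr.pair_rates[:] = rng.uniform(0.05, 0.5, (4, 4))
        proj._invalidate()
        act = normalize_softmax(rng.normal(size=4), pop.layout)
        pop.activity = act
        got = proj.support_term(act)
        w = compute_weights(tr, proj.lambda_0)
        for j in range(4):
            expected = math.log(tr.post_rates[j])
            for hc in ([0, 1], [2, 3]):
                expected += math.log(sum(w[i, j] * act[i] for i in hc))
            assert abs(got[j] - expected) < 1e-12

    def test_singleton_evidence_for_kwta_pre(self):
        """Non-modular pre: one log-weight term per active (binary) pre unit."""
        hip = Population(HypercolumnLayout.flat(20), PopulationParams(activity_level=0.1), k=2)
        proj = Projection(hip, hip, tau=INF, gain=1.0)
        rng = np.random.default_rng(9)
        proj.traces.pre_rates[:] = rng.uniform(0.05, 0.9, 20)
        proj.traces.pair_rates[:] = rng.uniform(0.01, 0.5, (20, 20))
        proj._invalidate()
        act = np.zeros(20)
        act[[3, 11]] = 1.0
        got = proj.support_term(act, active=np.array([3, 11]))
        w = compute_weights(proj.traces, proj.lambda_0)
        expected = np.log(proj.traces.post_rates) + np.log(w[3]) + np.log(w[11])
        assert np.allclose(got, expected, atol=1e-12)

    def test_fixed_projection_log_drive(self):
        pre = small_population(n_hc=1, size=4)
        post = small_population(n_hc=1, size=2)
        W = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5], [0.0, 0.0]])
        proj = FixedProjection(pre, post, W)
        act = np.array([0.4, 0.3, 0.2, 0.1])
        got = proj.support_term(act)
        assert np.allclose(got, np.log(W.T @ act), atol=1e-12)


class TestStepPopulation:
    def test_no_input_fixed_point_is_uniform(self):
        pop = small_population(n_hc=2, size=5)
        pop.activity = np.zeros(10)
        pop.activity[[0, 5]] = 1.0
        proj = Projection(pop, pop, tau=INF, gain=0.0)
        step_population(pop, [proj])
        assert np.allclose(pop.activity, 0.2, atol=1e-9)

    def test_clamp_overrides_activity_exactly(self):
        pop = small_population(n_hc=2, size=5)
        clamp = np.zeros(10)
        clamp[[2, 7]] = 1.0
        step_population(pop, [Projection(pop, pop, tau=50.0, gain=1.0)], clamp=clamp)
        assert np.array_equal(pop.activity, clamp)

    def test_single_trained_pattern_is_a_perfect_attractor(self):
        pop = small_population(n_hc=5, size=10)
        auto = Projection(pop, pop, tau=50.0, gain=1.0)
        pattern = np.zeros(50)
        pattern[np.arange(5) * 10 + 3] = 1.0
        for _ in range(100):
            step_population(pop, [auto], clamp=pattern)
        auto.tau = INF
        pop.activity = pattern.copy()
        for _ in range(10):
            step_population(pop, [auto])
        cos = pop.activity @ pattern / (np.linalg.norm(pop.activity) * np.linalg.norm(pattern))
        assert 0.5 * (1 - cos) < 1e-6

    def test_frozen_projections_are_bit_identical_after_1000_steps(self):
        pop = small_population(n_hc=2, size=5)
        auto = Projection(pop, pop, tau=INF, gain=1.0)
        adapt = Projection(pop, pop, tau=INF, gain=-1.0)
        snaps = [
            (p.weights.copy(), p.bias.copy(), p.traces.pair_rates.copy())
            for p in (auto, adapt)
        ]
        for _ in range(1000):
            step_population(pop, [auto, adapt])
        for p, (w, b, pair) in zip((auto, adapt), snaps):
            assert np.array_equal(p.weights, w)
            assert np.array_equal(p.bias, b)
            assert np.array_equal(p.traces.pair_rates, pair)

    def test_normalization_holds_after_every_step(self):
        pop = small_population(n_hc=3, size=4)
        auto = Projection(pop, pop, tau=30.0, gain=1.0)
        adapt = Projection(pop, pop, tau=100.0, gain=-1.2)
        rng = np.random.default_rng(2)
        for _ in range(50):
            step_population(pop, [auto, adapt])
            sums = pop.activity.reshape(3, 4).sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-9)
            assert np.all(np.isfinite(auto.weights)) and np.all(auto.weights > 0)
            assert np.all(np.isfinite(auto.bias))


class TestDeferredUpdates:
    def test_buffered_flush_equals_stepwise_updates(self):
        """A phase worth of buffered observations collapses to the same traces."""
        rng = np.random.default_rng(4)
        pop = small_population(n_hc=2, size=3)
        a = Projection(pop, pop, tau=37.0, gain=1.0)
        b = Projection(pop, pop, tau=37.0, gain=1.0)
        acts = [rng.uniform(0, 1, 6) for _ in range(25)]
        mults = rng.uniform(0.5, 2.0, 25)
        for act, m in zip(acts, mults):
            a.observe(act, act, dt=10.0, rate_multiplier=m)
            update_traces(b.traces, act, act, tau=37.0, dt=10.0, rate_multiplier=m)
        a.flush()
        assert np.allclose(a.traces.pre_rates, b.traces.pre_rates, atol=1e-12)
        assert np.allclose(a.traces.pair_rates, b.traces.pair_rates, atol=1e-12)
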