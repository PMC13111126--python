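"""Markov-population engine: tau-leaping, exact SSA oracle, mean-field ODE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from caru.engine import (
    ChannelPopulation,
    RateSpec,
    deterministic_step,
    ssa_exact,
    tau_leap_step,
    transition_probability,
)


class TestTransitionProbability:
    @pytest.mark.parametrize(
        "k, dt, expected",
        [
            (0.0, 0.001, 0.0),
            (0.060, 0.001, 5.999820003599928e-05),  # 1 - exp(-6e-5)
            (1e9, 0.001, 1.0),  # saturation
        ],
    )
    def test_values(self, k, dt, expected):
        assert transition_probability(k, dt) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            transition_probability(-1.0, 0.001)
        with pytest.raises(ValueError):
            transition_probability(1.0, 0.0)

    @given(
        k=st.floats(0.0, 1e3), dt=st.floats(1e-6, 10.0),
        k2=st.floats(0.0, 1e3), dt2=st.floats(1e-6, 10.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_and_bounded(self, k, dt, k2, dt2):
        p = transition_probability(k, dt)
        assert 0.0 <= p <= 1.0
        if k2 >= k:
            assert transition_probability(k2, dt) >= p
        if dt2 >= dt:
            assert transition_probability(k, dt2) >= p


class TestTauLeap:
    def test_zero_rates_unchanged(self, pop_a, rng):
        spec = RateSpec(("A", "B"), edges=[(0, 1)], rates=[0.0])
        out = tau_leap_step(pop_a, spec, 0.001, rng)
        assert (out.counts == pop_a.counts).all()

    def test_conservation_property(self, three_state, rng):
        """Channel number is conserved exactly over many steps."""
        pop = ChannelPopulation.stochastic_init(three_state.state_names, 500, "A")
        for _ in range(2000):
            pop = tau_leap_step(pop, three_state, 0.01, rng)
            assert pop.counts.sum() == 500
            assert (pop.counts >= 0).all()

    def test_binomial_moments(self, rng):
        """Mean movers over repeated single-transition leaps match
        n*(1 - exp(-k*dt)) within 3 standard errors."""
        n, k, dt, reps = 10_000, 1.0, 0.001, 10_000
        spec = RateSpec(("A", "B"), edges=[(0, 1)], rates=[k])
        p = -np.expm1(-k * dt)
        movers = np.empty(reps)
        for i in range(reps):
            pop = ChannelPopulation.stochastic_init(("A", "B"), n, "A")
            movers[i] = tau_leap_step(pop, spec, dt, rng).counts[1]
        se = np.sqrt(n * p * (1 - p) / reps)
        assert abs(movers.mean() - n * p) < 3 * se
        # variance should match the binomial variance within 10%
        assert movers.var() == pytest.approx(n * p * (1 - p), rel=0.1)

    def test_multinomial_partition_marginals(self, rng):
        """With two competing exits the per-edge counts keep binomial
        marginals p_i = (1-exp(-k_tot dt)) k_i/k_tot."""
        n, dt, reps = 5000, 0.01, 4000
        spec = RateSpec(("A", "B", "C"), edges=[(0, 1), (0, 2)], rates=[30.0, 10.0])
        k_tot = 40.0
        got = np.zeros((reps, 2))
        for i in range(reps):
            pop = ChannelPopulation.stochastic_init(("A", "B", "C"), n, "A")
            out = tau_leap_step(pop, spec, dt, rng)
            got[i] = out.counts[1], out.counts[2]
        p_leave = -np.expm1(-k_tot * dt)
        for j, k in enumerate([30.0, 10.0]):
            p = p_leave * k / k_tot
            se = np.sqrt(n * p * (1 - p) / reps)
            assert abs(got[:, j].mean() - n * p) < 3 * se

    def test_rejects_deterministic_population(self, two_state):
        pop = ChannelPopulation(("A", "B"), fractions=[0.5, 0.5])
        with pytest.raises(ValueError):
            tau_leap_step(pop, two_state, 0.001, np.random.default_rng(0))

    def test_bit_reproducible(self, three_state):
        def run(seed):
            rng = np.random.default_rng(seed)
            pop = ChannelPopulation.stochastic_init(three_state.state_names, 200, "A")
            hist = []
            for _ in range(500):
                pop = tau_leap_step(pop, three_state, 0.01, rng)
                hist.append(pop.counts.copy())
            return np.array(hist)

        assert (run(7) == run(7)).all()
        assert (run(7) != run(8)).any()


class TestSSA:
    def test_zero_rates_constant(self, rng):
        spec = RateSpec(("A", "B"), edges=[(0, 1)], rates=[0.0])
        pop = ChannelPopulation.stochastic_init(("A", "B"), 50, "A")
        times, traj = ssa_exact(pop, spec, 10.0, rng)
        assert len(times) == 1 and (traj[0] == pop.counts).all()

    def test_t_end_validation(self, two_state, pop_a, rng):
        with pytest.raises(ValueError):
            ssa_exact(pop_a, two_state, 0.0, rng)

    def test_exponential_decay(self, rng):
        """Source occupancy of an irreversible A->B decays as exp(-kt)."""
        k, t_end, n, reps = 0.5, 2.0, 40, 1500
        spec = RateSpec(("A", "B"), edges=[(0, 1)], rates=[k])
        survivors = np.empty(reps)
        for i in range(reps):
            pop = ChannelPopulation.stochastic_init(("A", "B"), n, "A")
            _, traj = ssa_exact(pop, spec, t_end, rng)
            survivors[i] = traj[-1][0]
        p = np.exp(-k * t_end)
        se = np.sqrt(n * p * (1 - p) / reps)
        assert abs(survivors.mean() - n * p) < 3 * se

    def test_tau_leap_agrees_with_ssa(self, three_state, rng):
        """Two-sample KS test at the 1% level on the occupancy of state A
        of a 3-state toy after 5 ms, tau-leap at dt = 0.001 ms vs SSA."""
        n, t_end, reps = 80, 2.0, 250
        dt = 0.001
        n_steps = int(round(t_end / dt))
        ssa_final = np.empty(reps)
        tau_final = np.empty(reps)
        for i in range(reps):
            pop = ChannelPopulation.stochastic_init(three_state.state_names, n, "A")
            _, traj = ssa_exact(pop, three_state, t_end, rng)
            ssa_final[i] = traj[-1][0]
        for i in range(reps):
            pop = ChannelPopulation.stochastic_init(three_state.state_names, n, "A")
            counts = pop.counts
            # vectorized equivalent of iterating tau_leap_step dt-by-dt
            for _ in range(n_steps):
                pop = tau_leap_step(pop, three_state, dt, rng)
            tau_final[i] = pop.counts[0]
        assert stats.ks_2samp(ssa_final, tau_final).pvalue > 0.01


class TestDeterministic:
    def test_zero_rates_identity(self):
        spec = RateSpec(("A", "B"), edges=[(0, 1)], rates=[0.0])
        x = np.array([0.3, 0.7])
        assert (deterministic_step(x, spec, 0.001) == x).all()

    def test_two_state_equilibrium(self, two_state):
        """Iterated to steady state, state B holds k12/(k12+k21) = 0.75."""
        x = np.array([1.0, 0.0])
        for _ in range(20000):
            x = deterministic_step(x, two_state, 0.01)
        assert x[1] == pytest.approx(0.3 / 0.4, abs=1e-6)

    @given(
        x0=st.floats(0.0, 1.0),
        k12=st.floats(0.0, 5.0),
        k21=st.floats(0.0, 5.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_sum_preserved(self, x0, k12, k21):
        spec = RateSpec(("A", "B"), edges=[(0, 1), (1, 0)], rates=[k12, k21])
        x = np.array([x0, 1.0 - x0])
        for _ in range(10):
            x = deterministic_step(x, spec, 0.01)
        assert x.sum() == pytest.approx(1.0, abs=1e-10)

    def test_euler_error_order_dt(self, two_state):
        """Relaxation error vs the closed form shrinks linearly with dt."""
        k_tot = 0.4
        t_end = 5.0
        exact = 0.75 * (1 - np.exp(-k_tot * t_end))  # occupancy of B

        def err(dt):
            x = np.array([1.0, 0.0])
            for _ in range(int(round(t_end / dt))):
                x = deterministic_step(x, two_state, dt)
            return abs(x[1] - exact)

        e1, e2 = err(0.02), err(0.01)
        assert e1 / e2 == pytest.approx(2.0, rel=0.2)

    def test_instability_error(self):
        spec = RateSpec(("A", "B"), edges=[(0, 1)], rates=[100.0])
        with pytest.raises(FloatingPointError):
            deterministic_step(np.array([1.0, 0.0]), spec, 0.05)


class TestContainers:
    def test_population_invariants(self):
        with pytest.raises(ValueError):
            ChannelPopulation(("A", "B"), counts=[-1, 2])
        with pytest.raises(ValueError):
            ChannelPopulation(("A", "B"), counts=[1, 2], total=5)
        with pytest.raises(ValueError):
            ChannelPopulation(("A", "B"), fractions=[0.6, 0.6])
        with pytest.raises(ValueError):
            ChannelPopulation(("A", "B"), counts=[1, 1], fractions=[0.5, 0.5])

    def test_rate_spec_invariants(self):
        with pytest.raises(ValueError):
            RateSpec(("A", "B"), edges=[(0, 0)], rates=[1.0])
        with pytest.raises(ValueError):
            RateSpec(("A", "B"), edges=[(0, 2)], rates=[1.0])
        with pytest.raises(ValueError):
            RateSpec(("A", "B"), edges=[(0, 1)], rates=[-1.0])
        with pytest.raises(ValueError):
            RateSpec(("A", "B"), edges=[(0, 1)], rates=[np.inf])
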