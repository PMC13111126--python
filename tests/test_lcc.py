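"""Seven-state L-type channel scheme: regulation hooks, GHK current,
and stochastic/deterministic agreement."""

import numpy as np
import pytest

from caru.engine import (
    ChannelPopulation,
    deterministic_step,
    tau_leap_step,
)
from caru.lcc import LCC_STATES, ical_current, lcc_rates
from caru.parameters import LCCParameters


CONTROL = LCCParameters()


def _rate_dict(spec):
    return {
        (spec.state_names[s], spec.state_names[t]): k
        for (s, t), k in zip(spec.edges, spec.rates)
    }


class TestRates:
    def test_control_scheme_well_formed(self):
        spec = lcc_rates(-80.0, 0.0002, CONTROL)
        assert spec.state_names == LCC_STATES
        assert (spec.rates >= 0).all()

    @pytest.mark.parametrize("v", np.linspace(-100, 80, 19))
    @pytest.mark.parametrize("ca_ss", [0.0, 0.0002, 0.5, 10.0])
    def test_rates_finite_over_physical_range(self, v, ca_ss):
        spec = lcc_rates(float(v), ca_ss, CONTROL)
        assert np.isfinite(spec.rates).all()

    def test_eta_scales_inactivation_edges_only(self):
        """eta = 0.5 exactly halves every f-/f2- edge and nothing else."""
        v, ca = -10.0, 0.001
        base = _rate_dict(lcc_rates(v, ca, CONTROL))
        half = _rate_dict(lcc_rates(v, ca, LCCParameters(eta=0.5)))
        eta_edges = {("O", "If"), ("O", "If2"), ("ICa", "IfCa"), ("Cp", "If")}
        for edge, k in base.items():
            if edge in eta_edges:
                assert half[edge] == pytest.approx(0.5 * k, rel=1e-12)
            else:
                assert half[edge] == pytest.approx(k, rel=1e-12)

    def test_phi_scales_opening_edge_only(self):
        """phi = 2 exactly doubles C'->O and leaves all other edges."""
        v, ca = 0.0, 0.0005
        base = _rate_dict(lcc_rates(v, ca, CONTROL))
        double = _rate_dict(lcc_rates(v, ca, LCCParameters(phi=2.0)))
        for edge, k in base.items():
            if edge == ("Cp", "O"):
                assert double[edge] == pytest.approx(2.0 * k, rel=1e-12)
            else:
                assert double[edge] == pytest.approx(k, rel=1e-12)

    def test_identity_at_control(self):
        a = lcc_rates(-20.0, 0.01, CONTROL)
        b = lcc_rates(-20.0, 0.01, LCCParameters(eta=1.0, phi=1.0))
        assert np.allclose(a.rates, b.rates)


class TestCurrent:
    def test_zero_open_fraction(self):
        assert ical_current(0.0, 0.0, 0.001, CONTROL) == 0.0

    def test_driving_term_zero(self):
        """The current vanishes when 0.25*Ca_ss*exp(z) equals Ca_o."""
        v = 40.0
        c = CONTROL.constants
        z = 2.0 * (v - 15.0) * c.F / (c.R * c.T)
        ca_ss = CONTROL.ca_o / (0.25 * np.exp(z))
        assert ical_current(0.5, v, ca_ss, CONTROL) == pytest.approx(0.0, abs=1e-12)

    def test_removable_singularity_series(self):
        """Either side of the series window the direct GHK evaluation
        agrees with the truncated series (L'Hopital oracle) to 6
        significant digits, and the current is continuous through
        DV = 0."""
        c = CONTROL.constants
        g = CONTROL.g_cal * CONTROL.gain
        for dv in (2e-4, -2e-4):  # just outside the |z| < 1e-5 window
            z = 2.0 * dv * c.F / (c.R * c.T)
            assert abs(z) > 1e-5
            series = (
                g * 2.0 * c.F
                * (0.25 * 0.0002 * np.exp(z) - CONTROL.ca_o)
                * (1.0 - z / 2.0 + z * z / 12.0)
            )
            direct = ical_current(1.0, 15.0 + dv, 0.0002, CONTROL)
            assert direct == pytest.approx(series, rel=1e-6)
        at_zero = ical_current(1.0, 15.0, 0.0002, CONTROL)
        just_off = ical_current(1.0, 15.0 + 1e-7, 0.0002, CONTROL)
        assert just_off == pytest.approx(at_zero, rel=1e-7)

    def test_proportional_to_open_fraction(self):
        i1 = ical_current(0.25, -10.0, 0.001, CONTROL)
        i2 = ical_current(0.5, -10.0, 0.001, CONTROL)
        assert i2 == pytest.approx(2.0 * i1, rel=1e-12)

    def test_open_fraction_domain(self):
        with pytest.raises(ValueError):
            ical_current(1.5, 0.0, 0.001, CONTROL)

    def test_inward_at_plateau_voltages(self):
        assert ical_current(0.3, 0.0, 0.0002, CONTROL) < 0.0


class TestDynamics:
    def _det_occupancy(self, v, ca, t_end=200.0, dt=0.01, params=CONTROL):
        spec = lcc_rates(v, ca, params)
        x = np.zeros(7)
        x[0] = 1.0
        for _ in range(int(t_end / dt)):
            x = deterministic_step(x, spec, dt)
        return x

    def test_clamp_peak_and_decay(self):
        """At a depolarizing clamp the open fraction rises to a peak and
        then decays (voltage/calcium-dependent inactivation)."""
        spec = lcc_rates(0.0, 0.0002, CONTROL)
        x = np.zeros(7)
        x[0] = 1.0
        dt = 0.01
        trace = []
        for _ in range(int(300.0 / dt)):
            x = deterministic_step(x, spec, dt)
            trace.append(x[2])
        trace = np.array(trace)
        ip = trace.argmax()
        assert 0 < ip < len(trace) - 1
        assert trace[-1] < 0.5 * trace[ip]

    def test_peak_current_at_intermediate_clamp(self):
        """Peak inward current is largest at intermediate clamp voltages
        (I-V relation shape)."""
        def peak_i(v):
            spec = lcc_rates(v, 0.0002, CONTROL)
            x = np.zeros(7)
            x[0] = 1.0
            best = 0.0
            for _ in range(3000):
                x = deterministic_step(x, spec, 0.01)
                best = min(best, ical_current(x[2], v, 0.0002, CONTROL))
            return best

        i_low, i_mid, i_high = peak_i(-40.0), peak_i(0.0), peak_i(60.0)
        assert i_mid < i_low and i_mid < i_high

    def test_calcium_accelerates_inactivation(self):
        """Raising subspace calcium lowers the late open fraction."""
        lo = self._det_occupancy(0.0, 0.0002)[2]
        hi = self._det_occupancy(0.0, 0.5)[2]
        assert hi < lo

    def test_stochastic_mean_matches_deterministic(self, rng):
        """Frozen (V, Ca): the replicate-averaged open fraction of 10^4
        channels after a fixed horizon matches the deterministic
        occupancy run with the identical step sequence, within 3 SE of
        the mean-field binomial fluctuation."""
        v, ca, dt, n, horizon, reps = -5.0, 0.001, 0.02, 10_000, 2500, 8
        spec = lcc_rates(v, ca, CONTROL)
        x = np.zeros(7)
        x[0] = 1.0
        for _ in range(horizon):
            x = deterministic_step(x, spec, dt)
        det_open = x[2]
        means = []
        for _ in range(reps):
            pop = ChannelPopulation.stochastic_init(LCC_STATES, n, "C")
            for _ in range(horizon):
                pop = tau_leap_step(pop, spec, dt, rng)
            means.append(pop.counts[2] / n)
        se = np.sqrt(det_open * (1 - det_open) / n / reps)
        assert abs(np.mean(means) - det_open) < 3 * se
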