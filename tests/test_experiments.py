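"""Release statistic, APD measurement, protocol arithmetic, dispersion
and modality analysis, transition detection."""

import numpy as np
import pytest

from caru.config import SimulationConfig
from caru.experiments import (
    BeatSummary,
    apd,
    beat_release_integral,
    detect_transition,
    dispersion_and_modes,
)


class TestReleaseIntegral:
    def test_constant_flux(self):
        """Constant flux c over period T integrates to c*T."""
        dt, n = 0.001, 100_000
        c = 0.037
        assert beat_release_integral(np.full(n, c), dt) == pytest.approx(
            c * n * dt, rel=1e-12
        )

    def test_zero_flux(self):
        assert beat_release_integral(np.zeros(1000), 0.001) == 0.0

    def test_half_sine(self):
        """Half-sine of amplitude A over T integrates to 2AT/pi."""
        T, n, A = 1000.0, 1_000_000, 0.05
        dt = T / n
        t = np.arange(n) * dt
        trace = A * np.sin(np.pi * t / T)
        assert beat_release_integral(trace, dt) == pytest.approx(
            2 * A * T / np.pi, rel=1e-4
        )

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            beat_release_integral(np.array([]), 0.001)


class TestAPD:
    def test_rectangular_pulse(self):
        """A rectangular AP of width w has APD50 = APD90 = w."""
        dt = 0.01
        v = np.full(30_000, -85.0)
        w = 120.0
        v[100 : 100 + int(w / dt)] = 20.0
        assert apd(v, 0.5, dt) == pytest.approx(w, abs=2 * dt)
        assert apd(v, 0.9, dt) == pytest.approx(w, abs=2 * dt)

    def test_triangular_geometry_oracle(self):
        """Triangular AP: upstroke jump to peak then linear decline of
        slope -s; the f-crossing time is f*(Vp - Vd)/s after the peak."""
        dt = 0.01
        vd, vp, slope = -80.0, 40.0, 0.5  # mV, mV, mV/ms
        n = 40_000
        t = np.arange(n) * dt
        v = np.full(n, vd)
        up = 500  # upstroke sample
        dur = (vp - vd) / slope
        mask = t >= t[up]
        v[mask] = np.maximum(vp - slope * (t[mask] - t[up]), vd)
        for f in (0.5, 0.9):
            expected = f * (vp - vd) / slope
            assert apd(v, f, dt) == pytest.approx(expected, abs=2 * dt)

    def test_apd90_geq_apd50(self):
        rng = np.random.default_rng(0)
        dt = 0.01
        t = np.arange(50_000) * dt
        v = -85 + 125 * np.exp(-((t - 50) ** 2) / 2e4) * (t > 20)
        a50, a90 = apd(v, 0.5, dt), apd(v, 0.9, dt)
        assert a90 >= a50 >= 0

    def test_no_crossing_returns_nan(self):
        """A trace that never repolarizes is flagged, not an error."""
        dt = 0.01
        v = np.concatenate([np.full(100, -85.0), np.full(5000, 10.0)])
        assert np.isnan(apd(v, 0.9, dt))

    def test_fraction_domain(self):
        with pytest.raises(ValueError):
            apd(np.zeros(100), 1.5, 0.01)


class TestProtocolArithmetic:
    def test_full_scale_retains_1000(self):
        """The standard protocol (1100 total, 100 discarded) analyzes
        exactly 1000 beats."""
        cfg = SimulationConfig(total_beats=1100, discard_beats=100)
        assert cfg.validate().analyzed_beats == 1000

    def test_scaled_protocol(self):
        cfg = SimulationConfig(total_beats=60, discard_beats=10)
        assert cfg.validate().analyzed_beats == 50

    def test_degenerate_discard_rejected(self):
        with pytest.raises(ValueError, match="analyzed beat"):
            SimulationConfig(total_beats=50, discard_beats=50).validate()

    def test_beat_summary_invariants(self):
        with pytest.raises(ValueError):
            BeatSummary(0, -1.0, 100.0, 200.0, 1e-3, 3.6)
        with pytest.raises(ValueError):
            BeatSummary(0, 1.0, 300.0, 200.0, 1e-3, 3.6)


class TestDispersionAndModes:
    def test_degenerate_samples(self):
        out = dispersion_and_modes(np.full(10, 2.5))
        assert out.rel_dispersion == 0.0
        assert out.n_modes == 1
        assert out.mode_locations == (2.5,)

    def test_minimum_samples(self):
        with pytest.raises(ValueError):
            dispersion_and_modes(np.arange(10.0))

    def test_two_separated_clusters(self):
        """6-sigma separated Gaussian clusters: two modes recovered at
        the cluster means within sigma/sqrt(n)."""
        rng = np.random.default_rng(42)
        sigma = 0.2
        a = rng.normal(2.0, sigma, 300)
        b = rng.normal(2.0 + 6 * sigma, sigma, 200)
        out = dispersion_and_modes(np.concatenate([a, b]))
        assert out.n_modes == 2
        tol = 4 * sigma / np.sqrt(200)
        assert out.mode_locations[0] == pytest.approx(2.0, abs=3 * tol)
        assert out.mode_locations[1] == pytest.approx(3.2, abs=3 * tol)

    def test_single_gaussian(self):
        rng = np.random.default_rng(7)
        out = dispersion_and_modes(rng.normal(3.0, 0.3, 500))
        assert out.n_modes == 1
        assert out.rel_dispersion == pytest.approx(
            2 * 0.6745 * 0.3 / 3.0, rel=0.15
        )  # IQR of a normal is 1.349 sigma


class TestDetectTransition:
    def test_sampling_noise_null(self):
        """A pure 1/sqrt(N) dispersion curve (fold sqrt(2) per doubling)
        flags no transition."""
        n = np.array([16, 32, 64, 128, 256, 512])
        d = 1.0 / np.sqrt(n)
        out = detect_transition(n, d)
        assert out.n_star is None
        assert max(out.fold_reductions) == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_constructed_step(self):
        """A 10x drop between 128 and 256 places the transition at 128."""
        n = np.array([16, 32, 64, 128, 256, 512])
        d = np.array([0.5, 0.36, 0.25, 0.18, 0.018, 0.013])
        out = detect_transition(n, d)
        assert out.n_star == 128

    def test_input_validation(self):
        with pytest.raises(ValueError):
            detect_transition([16, 32, 64], [1, 2, 3])
        with pytest.raises(ValueError):
            detect_transition([16, 32, 32, 64], [1, 1, 1, 1])
        with pytest.raises(ValueError):
            detect_transition([16, 32, 64, 128], [1, 1, 1])
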