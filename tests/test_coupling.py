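import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from golfswing import coupling, kinematics, synthetic
from golfswing.coupling import (
    PhaseUndefinedError,
    align_and_normalize,
    centered_hilbert_phase,
    crp_series,
    trial_crp_curve,
)


class TestHilbertPhase:
    def test_cosine_phase_is_linear(self):
        """The analytic signal of a cosine is a unit phasor: phase advances
        360 deg per period, within 2 deg on the central 60% of samples."""
        n, f = 500, 5.0
        t = np.arange(n) / n
        ph = centered_hilbert_phase(np.cos(2 * np.pi * f * t))
        ideal = ph[n // 2] + 360.0 * f * (t - t[n // 2])
        central = slice(int(0.2 * n), int(0.8 * n))
        assert np.abs(ph - ideal)[central].max() <= 2.0

    def test_centering_invariance(self):
        t = np.linspace(0, 1, 256)
        x = np.sin(2 * np.pi * 4 * t)
        np.testing.assert_allclose(centered_hilbert_phase(x),
                                   centered_hilbert_phase(x + 7.3), atol=1e-9)

    def test_constant_signal_rejected(self):
        with pytest.raises(PhaseUndefinedError):
            centered_hilbert_phase(np.full(64, 3.3))

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            centered_hilbert_phase(np.arange(8.0))

    def test_edge_artifacts_confined_to_outer_tenth(self):
        """With mirror padding the Gibbs error exceeds 2 deg only in the
        outer 10% of samples."""
        n, f = 500, 5.0
        t = np.arange(n) / n
        ph = centered_hilbert_phase(np.cos(2 * np.pi * f * t))
        ideal = ph[n // 2] + 360.0 * f * (t - t[n // 2])
        err = np.abs(ph - ideal)
        inner = slice(n // 10, n - n // 10)
        assert err[inner].max() <= 2.0


class TestCRPSeries:
    def test_identical_signals_zero(self):
        t = np.linspace(0, 1, 300)
        x = np.sin(2 * np.pi * 3 * t)
        np.testing.assert_allclose(crp_series(x, x), 0.0, atol=1e-9)

    def test_thirty_degree_lag_recovered(self):
        """sin(wt) leads sin(wt - 30 deg) by 30 deg of phase."""
        n, f = 800, 8.0
        t = np.linspace(0, 1, n)
        a = np.sin(2 * np.pi * f * t)
        b = np.sin(2 * np.pi * f * t - np.radians(30))
        crp = crp_series(a, b)
        central = crp[int(0.2 * n):int(0.8 * n)]
        assert np.abs(central - 30.0).max() <= 3.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(f=st.floats(3, 9), lag=st.floats(5, 90))
    def test_antisymmetry(self, f, lag):
        t = np.linspace(0, 1, 512)
        a = np.sin(2 * np.pi * f * t)
        b = np.sin(2 * np.pi * f * t - np.radians(lag))
        np.testing.assert_allclose(crp_series(a, b), -crp_series(b, a),
                                   atol=1e-9)

    def test_negate_flag(self):
        t = np.linspace(0, 1, 400)
        a = np.sin(2 * np.pi * 4 * t)
        b = np.cos(2 * np.pi * 4 * t)
        np.testing.assert_allclose(crp_series(a, b, negate=True),
                                   -crp_series(a, b), atol=1e-12)


class TestAlignAndNormalize:
    def _events(self, n):
        return kinematics.SwingEvents(0, n // 3, n - 1)

    def test_output_length_and_align_node(self):
        n = 467
        x = np.sin(np.linspace(0, 3, n))
        pelvis = -np.abs(np.linspace(-1, 1.2, n))  # max strictly inside
        curve = align_and_normalize(x, pelvis, self._events(n))
        assert len(curve.values) == 200
        assert curve.align_node == 99

    def test_piecewise_linear_series_resampled_exactly(self):
        n = 301
        m = 120
        pelvis = np.concatenate([np.linspace(0, 1, m + 1),
                                 np.linspace(1, -1, n - m)[1:]])
        series = 2.0 * np.arange(n)  # linear on both sub-segments
        ev = kinematics.SwingEvents(0, m, n - 1)
        curve = align_and_normalize(series, pelvis, ev)
        k = curve.align_node + 1
        np.testing.assert_allclose(curve.values[:k], np.linspace(0, 2 * m, k),
                                   rtol=1e-12)
        np.testing.assert_allclose(
            curve.values[k - 1:], np.linspace(2 * m, 2 * (n - 1), 200 - k + 1),
            rtol=1e-12)

    def test_align_node_holds_value_at_maximum(self):
        n = 400
        m = 170
        pelvis = np.concatenate([np.linspace(0, 5, m + 1),
                                 np.linspace(5, -3, n - m)[1:]])
        series = np.sin(np.arange(n) / 17.0)
        ev = kinematics.SwingEvents(0, m, n - 1)
        curve = align_and_normalize(series, pelvis, ev)
        assert curve.values[curve.align_node] == pytest.approx(series[m],
                                                               abs=1e-9)

    def test_no_interior_maximum_rejected(self):
        n = 100
        pelvis = np.linspace(0, 1, n)  # max at the boundary
        with pytest.raises(ValueError, match="interior maximum"):
            align_and_normalize(np.zeros(n), pelvis, self._events(n))

    def test_shift_strategy_same_length(self):
        n = 300
        pelvis = -np.abs(np.linspace(-1, 1.5, n))
        x = np.cos(np.linspace(0, 4, n))
        curve = align_and_normalize(x, pelvis, self._events(n), strategy="shift")
        assert len(curve.values) == 200


class TestTrialCRP:
    def test_identical_phase_construction(self, analyzed_noiseless):
        """Zero lag and zero noise: pelvis and thorax angles are exactly
        proportional, so CRP ~ 0 through the central 80% of the stroke."""
        curve = trial_crp_curve(analyzed_noiseless["angles"],
                                analyzed_noiseless["events"])
        assert np.abs(curve.values[20:180]).max() < 1.0

    def test_pelvis_lead_lag_monotone(self):
        """Pelvis reversal leading by tau: downswing CRP is positive with
        magnitude monotone in tau."""
        means = []
        for tau in (0.02, 0.04, 0.08):
            prof = synthetic.SwingProfile(transition_lead_s=tau)
            trial, _ = synthetic.generate_trial(prof, seed=1)
            ev = kinematics.detect_events(trial)
            ang = kinematics.segment_angles(trial)
            curve = trial_crp_curve(ang, ev)
            means.append(curve.values[curve.align_node + 10:190].mean())
        assert all(m > 0 for m in means)
        assert means[0] < means[1] < means[2]

    def test_onset_lag_makes_backswing_crp_negative(self):
        """A delayed pelvis start (male pattern) shows as negative CRP in
        the backswing, monotone in the lag."""
        means = []
        for lag in (0.0, 0.04, 0.08):
            prof = synthetic.SwingProfile(pelvis_onset_lag_s=lag)
            trial, _ = synthetic.generate_trial(prof, seed=1)
            ev = kinematics.detect_events(trial)
            ang = kinematics.segment_angles(trial)
            curve = trial_crp_curve(ang, ev)
            means.append(curve.values[10:90].mean())
        assert means[1] < means[0] and means[2] < means[1]
        assert means[1] < -0.5

    def test_time_scaling_invariance(self):
        """Generating the same swing at 100 vs 200 Hz changes the
        normalized CRP curve by no more than 2 deg RMS."""
        curves = []
        for fs in (100.0, 200.0):
            prof = synthetic.SwingProfile(pelvis_onset_lag_s=0.03,
                                          sample_rate=fs)
            trial, _ = synthetic.generate_trial(prof, seed=6)
            ev = kinematics.detect_events(trial)
            ang = kinematics.segment_angles(trial)
            curves.append(trial_crp_curve(ang, ev).values)
        rms = np.sqrt(np.mean((curves[0] - curves[1]) ** 2))
        assert rms <= 2.0
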