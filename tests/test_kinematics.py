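import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from golfswing import kinematics, synthetic
from golfswing.io import TrialRecording
from golfswing.kinematics import (
    SwingEvents,
    club_speed_accel,
    detect_events,
    extract_parameters,
    segment_angles,
)
from tests.conftest import make_static_trial


def _trial_from_angles(theta_deg):
    """Trial whose body markers are the setup geometry rotated per-frame."""
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    prof = synthetic.SwingProfile()
    base, _ = synthetic.generate_trial(prof, seed=0)
    n = len(theta)
    markers = {}
    for m in ("LASIS", "RASIS", "LPSIS", "RPSIS", "LACR", "RACR"):
        p = base.markers[m][0]
        markers[m] = np.column_stack([
            p[0] * np.cos(theta) - p[1] * np.sin(theta),
            p[0] * np.sin(theta) + p[1] * np.cos(theta),
            np.full(n, p[2]),
        ])
    for m in ("CLUB_GRIP", "CLUB_HEAD"):
        markers[m] = np.tile(base.markers[m][0], (n, 1))
    return TrialRecording("R", 1, 200.0, markers)


class TestSegmentAngles:
    def test_rigid_rotation_recovered_exactly(self):
        """A +30 deg rigid rotation about Z reads back as 30.000 deg."""
        trial = _trial_from_angles([0.0, 30.0, 30.0, 30.0])
        ang = segment_angles(trial, cutoff_hz=None)
        np.testing.assert_allclose(ang.pelvis_deg[1:], 30.0, atol=1e-9)
        np.testing.assert_allclose(ang.thorax_deg[1:], 30.0, atol=1e-9)

    def test_setup_frame_is_zero(self):
        trial = _trial_from_angles([0.0, 12.0, 25.0])
        ang = segment_angles(trial, cutoff_hz=None)
        assert ang.pelvis_deg[0] == pytest.approx(0.0, abs=1e-12)
        assert ang.thorax_deg[0] == pytest.approx(0.0, abs=1e-12)

    def test_rotate_and_return(self):
        trial = _trial_from_angles([0.0, 40.0, 0.0])
        ang = segment_angles(trial, cutoff_hz=None)
        assert ang.pelvis_deg[-1] == pytest.approx(0.0, abs=1e-9)

    def test_backswing_positive_convention(self):
        """Whatever the physical turn direction, backswing reads positive."""
        for sign in (+1.0, -1.0):
            trial = _trial_from_angles(sign * np.array([0.0, 20.0, 50.0, 20.0]))
            ang = segment_angles(trial, cutoff_hz=None)
            assert ang.thorax_deg[2] == pytest.approx(50.0, abs=1e-9)

    def test_degenerate_geometry_rejected(self, noiseless_trial):
        trial, _ = noiseless_trial
        markers = {m: v.copy() for m, v in trial.markers.items()}
        markers["LACR"] = markers["RACR"].copy()
        bad = TrialRecording("D", 1, 200.0, markers)
        with pytest.raises(kinematics.DegenerateGeometryError):
            segment_angles(bad, cutoff_hz=None)


class TestClubSpeedAccel:
    def _with_club_path(self, path):
        base = make_static_trial(n=len(path))
        markers = {m: v.copy() for m, v in base.markers.items()}
        markers["CLUB_HEAD"] = np.asarray(path, dtype=float)
        return TrialRecording("C", 1, 200.0, markers)

    def test_constant_velocity(self):
        t = np.arange(300) / 200.0
        path = np.column_stack([2.0 * t, np.zeros_like(t), np.zeros_like(t)])
        trial = self._with_club_path(path)
        speed, accel, _ = club_speed_accel(trial, cutoff_hz=None)
        np.testing.assert_allclose(speed, 2.0, atol=1e-9)
        np.testing.assert_allclose(accel[1:-1], 0.0, atol=1e-6)

    def test_circular_motion_closed_form(self):
        """|v| = r*omega and |a| = r*omega^2 for uniform circular motion."""
        r, omega = 1.5, 8.0
        t = np.arange(600) / 200.0
        path = np.column_stack([r * np.cos(omega * t), r * np.sin(omega * t),
                                np.zeros_like(t)])
        trial = self._with_club_path(path)
        speed, accel, _ = club_speed_accel(trial, cutoff_hz=None)
        inner = slice(2, -2)
        np.testing.assert_allclose(speed[inner], r * omega, rtol=1e-3)
        np.testing.assert_allclose(accel[inner], r * omega ** 2, rtol=2e-3)

    def test_stationary_marker(self):
        trial = make_static_trial(n=100)
        speed, _, _ = club_speed_accel(trial, cutoff_hz=None)
        np.testing.assert_allclose(speed, 0.0, atol=1e-12)

    def test_too_short_rejected(self):
        trial = make_static_trial(n=4)
        with pytest.raises(ValueError, match="5 frames"):
            club_speed_accel(trial)


class TestDetectEvents:
    def test_noiseless_events_within_one_frame(self, analyzed_noiseless):
        ev, truth = analyzed_noiseless["events"], analyzed_noiseless["truth"]
        assert abs(ev.start_frame - truth.events.start_frame) <= 1
        assert abs(ev.top_frame - truth.events.top_frame) <= 1
        assert abs(ev.impact_frame - truth.events.impact_frame) <= 1

    def test_static_trial_is_no_swing(self):
        with pytest.raises(kinematics.NoSwingError, match="no swing"):
            detect_events(make_static_trial())

    def test_ordering_holds_across_cohort(self):
        cohort, _ = synthetic.generate_cohort(3, 3, 3, seed=9)
        for trial in cohort.trials:
            ev = detect_events(trial)
            assert ev.start_frame < ev.top_frame < ev.impact_frame

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(dx=st.floats(-5, 5), dy=st.floats(-5, 5), dz=st.floats(-2, 2))
    def test_translation_invariance(self, dx, dy, dz):
        prof = synthetic.SwingProfile()
        trial, _ = synthetic.generate_trial(prof, seed=4)
        shifted = TrialRecording(
            "T", 1, trial.sample_rate,
            {m: v + np.array([dx, dy, dz]) for m, v in trial.markers.items()})
        assert detect_events(trial) == detect_events(shifted)


class TestExtractParameters:
    def test_noiseless_recovery(self, analyzed_noiseless):
        par, truth = analyzed_noiseless["params"], analyzed_noiseless["truth"]
        assert par.pmax_deg == pytest.approx(truth.parameters.pmax_deg, abs=0.5)
        assert par.tmax_deg == pytest.approx(truth.parameters.tmax_deg, abs=0.5)
        assert par.xfac_deg == pytest.approx(truth.parameters.xfac_deg, abs=0.5)
        assert par.gcv_mps == pytest.approx(truth.parameters.gcv_mps, abs=0.1)
        # simultaneous-peak construction: Xfac = Tmax - Pmax = 63.8
        assert par.xfac_deg == pytest.approx(63.8, abs=0.5)

    def test_xfac_equals_separation_at_top(self, analyzed_noiseless):
        ang, ev, par = (analyzed_noiseless["angles"], analyzed_noiseless["events"],
                        analyzed_noiseless["params"])
        sep = ang.thorax_deg[ev.top_frame] - ang.pelvis_deg[ev.top_frame]
        assert par.xfac_deg == sep

    def test_sxfac_zero_when_separation_peaks_at_top(self, analyzed_noiseless):
        assert analyzed_noiseless["params"].sxfac_deg == 0.0

    def test_pelvis_lead_produces_stretch(self):
        """Pelvis reversing 40 ms early grows the X-factor after the top."""
        prof = synthetic.SwingProfile(transition_lead_s=0.040)
        trial, _ = synthetic.generate_trial(prof, seed=2)
        ev = detect_events(trial)
        ang = segment_angles(trial)
        speed, _, _ = club_speed_accel(trial)
        par = extract_parameters(ang, ev, speed)
        assert par.sxfac_deg > 0.5
        # agrees with the direct max-minus-top computation on the series
        sep = ang.thorax_deg - ang.pelvis_deg
        direct = sep[ev.top_frame:ev.impact_frame + 1].max() - sep[ev.top_frame]
        assert par.sxfac_deg == pytest.approx(direct)

    def test_impact_before_top_rejected(self, analyzed_noiseless):
        ang, ev = analyzed_noiseless["angles"], analyzed_noiseless["events"]
        speed = analyzed_noiseless["speed"]
        with pytest.raises(ValueError):
            bad = SwingEvents(ev.start_frame, ev.impact_frame, ev.top_frame)
            extract_parameters(ang, bad, speed)


class TestRecoveryAtScale:
    def test_fifty_profile_parameter_recovery(self):
        """Noiseless sweep over 20-130 deg amplitudes: <=0.5 deg, <=0.1 m/s,
        events within one frame."""
        rng = np.random.default_rng(12345)
        worst = np.zeros(7)
        for k in range(50):
            prof = synthetic.SwingProfile(
                pmax_deg=20 + 110 * rng.random(),
                tmax_deg=20 + 110 * rng.random(),
                gcv_mps=18 + 14 * rng.random(),
            )
            trial, truth = synthetic.generate_trial(prof, seed=k)
            ev = detect_events(trial)
            ang = segment_angles(trial)
            speed, _, _ = club_speed_accel(trial)
            par = extract_parameters(ang, ev, speed)
            worst = np.maximum(worst, [
                abs(par.pmax_deg - truth.parameters.pmax_deg),
                abs(par.tmax_deg - truth.parameters.tmax_deg),
                abs(par.xfac_deg - truth.parameters.xfac_deg),
                abs(par.gcv_mps - truth.parameters.gcv_mps),
                abs(ev.start_frame - truth.events.start_frame),
                abs(ev.top_frame - truth.events.top_frame),
                abs(ev.impact_frame - truth.events.impact_frame),
            ])
        assert worst[0] <= 0.5 and worst[1] <= 0.5 and worst[2] <= 0.5
        assert worst[3] <= 0.1
        assert worst[4] <= 1 and worst[5] <= 1 and worst[6] <= 1

    def test_noise_robustness(self):
        """2 mm marker noise: parameter SD over 100 replicates stays small."""
        prof = synthetic.SwingProfile(pmax_deg=46.8, tmax_deg=110.6,
                                      gcv_mps=23.0, noise_sd_m=0.002)
        vals = []
        for k in range(100):
            trial, _ = synthetic.generate_trial(prof, seed=1000 + k)
            ev = detect_events(trial)
            ang = segment_angles(trial)
            speed, _, _ = club_speed_accel(trial)
            par = extract_parameters(ang, ev, speed)
            vals.append([par.pmax_deg, par.tmax_deg, par.xfac_deg, par.gcv_mps])
        sd = np.asarray(vals).std(axis=0, ddof=1)
        assert np.all(sd[:3] <= 1.5)
        assert sd[3] <= 0.3
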