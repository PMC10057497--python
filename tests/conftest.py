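import numpy as np
import pytest

from golfswing import kinematics, synthetic


@pytest.fixture(scope="session")
def female_profile() -> synthetic.SwingProfile:
    """Noiseless profile at the female group means (simultaneous peaks)."""
    return synthetic.SwingProfile(pmax_deg=46.8, tmax_deg=110.6, gcv_mps=23.0,
                                  noise_sd_m=0.0)


@pytest.fixture(scope="session")
def noiseless_trial(female_profile):
    trial, truth = synthetic.generate_trial(female_profile, "F01", 1, seed=1)
    return trial, truth


@pytest.fixture(scope="session")
def analyzed_noiseless(noiseless_trial):
    trial, truth = noiseless_trial
    events = kinematics.detect_events(trial)
    angles = kinematics.segment_angles(trial)
    speed, accel, vel = kinematics.club_speed_accel(trial)
    params = kinematics.extract_parameters(angles, events, speed)
    return dict(trial=trial, truth=truth, events=events, angles=angles,
                speed=speed, accel=accel, params=params)


@pytest.fixture(scope="session")
def small_cohort():
    """2F + 2M x 2 trials; enough for cohort-level plumbing tests."""
    return synthetic.generate_cohort(2, 2, 2, seed=11)


def make_static_trial(n: int = 400, offset=(0.0, 0.0, 0.0)):
    """A trial whose markers never move (no swing)."""
    prof = synthetic.SwingProfile()
    trial, _ = synthetic.generate_trial(prof, "S", 1, seed=0)
    markers = {m: np.tile(trial.markers[m][0] + np.asarray(offset), (n, 1))
               for m in trial.markers}
    from golfswing.io import TrialRecording
    return TrialRecording("S", 1, 200.0, markers)
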