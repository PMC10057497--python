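"""Transverse-plane segment angles, club kinematics, swing events, parameters.

Pelvis and thorax motion is reduced to a single rotation angle in the
horizontal (x-y) plane: the four-quadrant angle of the right-to-left marker
line, unwrapped and zeroed at the setup frame, with backswing rotation
(away from the target at +X) positive. The three swing events are defined
from the club-head marker alone:

* start  -- club speed first sustains 0.2 m/s moving away from the target,
* top    -- minimum club speed between start and the global speed peak,
* impact -- peak acceleration magnitude near the global speed peak, where
  the club decelerates abruptly on ball contact.

The five discrete parameters are Tmax, Pmax (segment rotation between start
and top), the X-factor (thorax minus pelvis at the top), the X-factor
stretch (post-top growth of that separation), and GCV (peak club speed in
the downswing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io import TrialRecording

#: Default zero-lag Gaussian low-pass cutoff for marker positions (Hz).
#: Applied before differentiation; without it, raw 200 Hz differentiation
#: noise would swamp the acceleration-peak impact detector. A Gaussian
#: kernel is used rather than a recursive (Butterworth) filter because its
#: strictly positive impulse response cannot ring: filtered speed never
#: overshoots the true peak near the abrupt impact deceleration, which
#: matters for club-velocity extraction.
DEFAULT_CUTOFF_HZ = 20.0

SPEED_START_THRESHOLD = 0.2    # m/s, club speed defining the start of the swing
START_SUSTAIN_S = 0.05         # s the threshold must remain exceeded (debounce)
IMPACT_WINDOW_S = 0.05         # s around the speed peak searched for impact
MIN_SWING_SPEED = 1.0          # m/s: below this the trial contains no swing
SLOPPY_TRANSITION_SPEED = 0.5  # m/s: warn if the top-of-backswing minimum exceeds


class NoSwingError(ValueError):
    """The trial's club-head marker never reaches swing speed."""


class DegenerateGeometryError(ValueError):
    """Left/right marker centroids coincide; segment line undefined."""


@dataclass
class AngleSeries:
    """Pelvis and thorax horizontal-plane rotation angles (degrees)."""

    pelvis_deg: np.ndarray
    thorax_deg: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.pelvis_deg = np.asarray(self.pelvis_deg, dtype=float)
        self.thorax_deg = np.asarray(self.thorax_deg, dtype=float)
        if self.pelvis_deg.shape != self.thorax_deg.shape:
            raise ValueError("pelvis and thorax series must have equal length")


@dataclass(frozen=True)
class SwingEvents:
    """Frame indices of swing start, top of backswing, and impact."""

    start_frame: int
    top_frame: int
    impact_frame: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_frame < self.top_frame < self.impact_frame):
            raise ValueError(
                f"events out of order: start={self.start_frame}, "
                f"top={self.top_frame}, impact={self.impact_frame}"
            )


@dataclass
class SwingParameters:
    """The five discrete swing outcomes for one trial."""

    tmax_deg: float
    pmax_deg: float
    xfac_deg: float
    sxfac_deg: float
    gcv_mps: float
    participant_id: str | None = None
    trial_index: int | None = None


def lowpass(positions: np.ndarray, sample_rate: float,
            cutoff_hz: float | None = DEFAULT_CUTOFF_HZ) -> np.ndarray:
    """Zero-lag Gaussian low-pass along axis 0 (None = off).

    The kernel SD is chosen so the -3 dB point of the Gaussian transfer
    function sits at ``cutoff_hz`` (sigma_t = sqrt(ln 2)/(2 pi f_c)).
    """
    if cutoff_hz is None:
        return np.asarray(positions, dtype=float)
    sigma_samples = np.sqrt(np.log(2.0)) / (2.0 * np.pi * cutoff_hz) * sample_rate
    return gaussian_filter1d(np.asarray(positions, dtype=float), sigma_samples,
                             axis=0, mode="nearest")


def _line_angle_deg(right: np.ndarray, left: np.ndarray, label: str) -> np.ndarray:
    """Unwrapped four-quadrant angle (deg) of the right-to-left line vs +X."""
    vec = left[:, :2] - right[:, :2]
    norms = np.linalg.norm(vec, axis=1)
    if np.any(norms < 1e-9):
        raise DegenerateGeometryError(
            f"{label}: left/right centroids coincide at frame "
            f"{int(np.argmax(norms < 1e-9))}"
        )
    return np.degrees(np.unwrap(np.arctan2(vec[:, 1], vec[:, 0])))


def segment_angles(
    trial: TrialRecording,
    *,
    cutoff_hz: float | None = DEFAULT_CUTOFF_HZ,
    setup_window_frames: int | None = None,
) -> AngleSeries:
    """Compute pelvis and thorax horizontal-plane rotation angles.

    The pelvis line runs from the right-side centroid (RASIS+RPSIS)/2 to the
    left-side centroid; the thorax line from RACR to LACR. Angles are zeroed
    at frame 0 (or at the mean of the first ``setup_window_frames``) and the
    sign is flipped, if needed, so backswing rotation is positive: the flip
    criterion is that the thorax's dominant excursion is positive.
    """
    filt = {m: lowpass(trial.markers[m], trial.sample_rate, cutoff_hz)
            for m in ("LASIS", "RASIS", "LPSIS", "RPSIS", "LACR", "RACR")}
    pelvis_right = 0.5 * (filt["RASIS"] + filt["RPSIS"])
    pelvis_left = 0.5 * (filt["LASIS"] + filt["LPSIS"])
    pelvis = _line_angle_deg(pelvis_right, pelvis_left, "pelvis")
    thorax = _line_angle_deg(filt["RACR"], filt["LACR"], "thorax")
    if setup_window_frames:
        pelvis = pelvis - pelvis[:setup_window_frames].mean()
        thorax = thorax - thorax[:setup_window_frames].mean()
    else:
        pelvis = pelvis - pelvis[0]
        thorax = thorax - thorax[0]
    # backswing-positive convention: the thorax's largest excursion defines it
    if thorax[np.argmax(np.abs(thorax))] < 0:
        pelvis, thorax = -pelvis, -thorax
    return AngleSeries(pelvis_deg=pelvis, thorax_deg=thorax,
                       sample_rate=trial.sample_rate)


def club_speed_accel(
    trial: TrialRecording,
    *,
    cutoff_hz: float | None = DEFAULT_CUTOFF_HZ,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Club-head speed, acceleration magnitude, and velocity vectors.

    Positions are low-pass filtered (zero lag), then differentiated with
    central differences (one-sided at the endpoints, via ``np.gradient``).
    Returns ``(speed, accel_magnitude, velocity)``.
    """
    if trial.n_frames < 5:
        raise ValueError(f"need at least 5 frames, got {trial.n_frames}")
    pos = lowpass(trial.markers["CLUB_HEAD"], trial.sample_rate, cutoff_hz)
    dt = 1.0 / trial.sample_rate
    vel = np.gradient(pos, dt, axis=0)
    acc = np.gradient(vel, dt, axis=0)
    return np.linalg.norm(vel, axis=1), np.linalg.norm(acc, axis=1), vel


def detect_events(
    trial: TrialRecording,
    *,
    cutoff_hz: float | None = DEFAULT_CUTOFF_HZ,
    target_direction: int = +1,
    speed_threshold: float = SPEED_START_THRESHOLD,
    sustain_s: float = START_SUSTAIN_S,
    impact_window_s: float = IMPACT_WINDOW_S,
) -> SwingEvents:
    """Detect swing start, top of backswing, and impact from club kinematics.

    ``target_direction`` is +1 when the target lies at +X (right-handed
    setup as recorded here); "away from the target" is then negative X
    velocity.
    """
    speed, accel, vel = club_speed_accel(trial, cutoff_hz=cutoff_hz)
    if speed.max() < MIN_SWING_SPEED:
        raise NoSwingError(
            f"no swing detected: peak club speed {speed.max():.3f} m/s "
            f"< {MIN_SWING_SPEED} m/s"
        )
    fs = trial.sample_rate
    sustain = max(1, int(round(sustain_s * fs)))
    above = speed >= speed_threshold
    # The threshold crossing that starts the swing is the one from which the
    # club accelerates without dropping back below threshold: trace back from
    # the first unambiguous swing frame to the most recent sub-threshold frame.
    swing = int(np.argmax(speed >= MIN_SWING_SPEED))
    below = np.flatnonzero(~above[:swing])
    if len(below) == 0:
        raise NoSwingError("club never rests below the start threshold")
    start = int(below[-1]) + 1
    if not above[start:start + sustain].all():
        raise NoSwingError("start-of-swing crossing not sustained")
    # moving away from the target (negative X velocity for a target at +X)
    going_away = -target_direction * vel[start:start + sustain, 0] > 0
    if not going_away.any():
        raise NoSwingError("club moves toward the target at swing start")
    peak = int(np.argmax(speed))
    if peak <= start + 1:
        raise NoSwingError("speed peak precedes start; not a swing")
    top = start + 1 + int(np.argmin(speed[start + 1:peak]))
    if speed[top] > SLOPPY_TRANSITION_SPEED:
        warnings.warn(
            f"sloppy backswing-downswing transition: minimum club speed "
            f"{speed[top]:.2f} m/s at frame {top}",
            stacklevel=2,
        )
    w = int(round(impact_window_s * fs))
    lo = max(top + 1, peak - w)
    hi = min(trial.n_frames, peak + w + 1)
    impact = lo + int(np.argmax(accel[lo:hi]))
    try:
        return SwingEvents(start_frame=start, top_frame=top, impact_frame=impact)
    except ValueError as exc:  # pragma: no cover - internal consistency
        raise RuntimeError(f"event detection produced inconsistent events: {exc}")


def extract_parameters(
    angles: AngleSeries,
    events: SwingEvents,
    club_speed: np.ndarray,
    *,
    participant_id: str | None = None,
    trial_index: int | None = None,
) -> SwingParameters:
    """Compute Tmax, Pmax, Xfac, SXfac, and GCV for one trial.

    Tmax/Pmax are the absolute segment rotations between the start and the
    top of the backswing; Xfac is the signed thorax-minus-pelvis separation
    at the top; SXfac is the largest post-top growth of that separation up
    to impact (floored at zero); GCV is the maximum club speed in
    ``(top, impact]``.
    """
    s, t, i = events.start_frame, events.top_frame, events.impact_frame
    if i <= t:
        raise ValueError("impact must follow the top of the backswing")
    pelvis, thorax = angles.pelvis_deg, angles.thorax_deg
    pmax = abs(pelvis[t] - pelvis[s])
    tmax = abs(thorax[t] - thorax[s])
    separation = thorax - pelvis
    xfac = float(separation[t])
    sxfac = max(0.0, float(separation[t:i + 1].max() - xfac))
    gcv = float(np.max(club_speed[t + 1:i + 1]))
    return SwingParameters(
        tmax_deg=float(tmax),
        pmax_deg=float(pmax),
        xfac_deg=xfac,
        sxfac_deg=sxfac,
        gcv_mps=gcv,
        participant_id=participant_id,
        trial_index=trial_index,
    )
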