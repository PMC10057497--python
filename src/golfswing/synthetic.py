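"""Synthetic golf swings with analytically known ground truth.

Pelvis and thorax rotation follow raised-cosine (cycloidal) ramps: zero at
setup, rising smoothly to the segment amplitude over the backswing, then
descending past zero into the follow-through. Raised cosines are C1-smooth
with flat ends and analytically known extrema, so every downstream quantity
(events, Tmax/Pmax/Xfac/SXfac/GCV, relative phase) has a closed form that
serves as the ground truth for testing.

Two timing parameters shape inter-segment coordination:

* ``pelvis_onset_lag_s`` -- the pelvis starts its backswing after the
  thorax (positive lag: thorax-led backswing, the male pattern reported for
  junior players; ~0 for the female pattern).
* ``transition_lead_s`` -- the pelvis reverses toward the target before the
  thorax does, which briefly grows the thorax-pelvis separation after the
  top and produces a positive X-factor stretch.

The club-head marker travels a horizontal circular arc about a vertical
axis; its radius is solved from the requested peak speed so the analytic
peak club-head speed equals ``gcv_mps`` exactly. The arc decelerates to rest
over a short raised-cosine stop window representing ball contact, giving
the sharp acceleration spike the impact detector keys on.

Sex presets carry the junior-elite group means and SDs for Pmax, Tmax and
GCV (8 girls / 6 boys study design); the onset-lag presets (M 40 ms, F 0 ms)
are simulator parameters expressing the qualitative coordination difference,
not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import Cohort, Participant, TrialRecording
from .kinematics import SwingEvents, SwingParameters

# Setup marker geometry (metres, local frame: +X toward target, +Y anterior).
PELVIS_HALF_WIDTH = 0.14
ASIS_ANTERIOR = 0.06        # ASIS/PSIS sit 0.12 m apart front-to-back
SHOULDER_HALF_WIDTH = 0.20
PELVIS_HEIGHT = 0.95
SHOULDER_HEIGHT = 1.45
CLUB_AXIS_XY = (0.0, 0.35)  # horizontal position of the swing axis
CLUB_HEAD_HEIGHT = 0.05
CLUB_GRIP_HEIGHT = 0.95
GRIP_RADIUS_FRACTION = 0.2  # grip marker radius as a fraction of head radius

TAIL_S = 0.15               # recording continues this long after the club stops


def _raised_cosine(u: np.ndarray) -> np.ndarray:
    """Smooth 0->1 ramp on [0, 1] with zero slope at both ends."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))


@dataclass
class SwingProfile:
    """Ground-truth kinematic recipe for one synthetic swing."""

    pmax_deg: float = 46.8            # pelvis rotation amplitude
    tmax_deg: float = 110.6           # thorax rotation amplitude
    backswing_s: float = 0.8
    downswing_s: float = 0.35
    pelvis_onset_lag_s: float = 0.0   # >0: pelvis starts after thorax
    transition_lead_s: float = 0.0    # >0: pelvis reverses before thorax
    gcv_mps: float = 23.0             # analytic peak club-head speed
    noise_sd_m: float = 0.0           # isotropic marker noise SD
    setup_hold_s: float = 0.5         # near-stationary pre-swing
    sample_rate: float = 200.0
    follow_ratio: float = 0.5         # segment follow-through amplitude fraction
    club_backswing_deg: float = 45.0
    club_follow_ratio: float = 0.6    # club overshoot fraction past impact
    impact_stop_s: float = 0.015      # raised-cosine deceleration window

    def __post_init__(self) -> None:
        if min(self.pmax_deg, self.tmax_deg) < 0:
            raise ValueError("amplitudes must be >= 0")
        if min(self.backswing_s, self.downswing_s, self.impact_stop_s) <= 0:
            raise ValueError("durations must be positive")
        if self.noise_sd_m < 0:
            raise ValueError("noise_sd_m must be >= 0")
        if self.gcv_mps <= 0:
            raise ValueError("gcv_mps must be positive")
        if self.transition_lead_s < 0:
            raise ValueError("transition_lead_s must be >= 0")
        pelvis_backswing = (self.backswing_s - self.transition_lead_s
                            - self.pelvis_onset_lag_s)
        if pelvis_backswing <= 0:
            raise ValueError("pelvis backswing duration is non-positive")

    # ---- analytic building blocks -------------------------------------

    @property
    def t_thorax_start(self) -> float:
        return self.setup_hold_s

    @property
    def t_top(self) -> float:
        return self.setup_hold_s + self.backswing_s

    def _club_geometry(self) -> tuple[float, float, float, float]:
        """(Phi, Phi_follow, impact_offset_s, head_radius)."""
        phi = np.radians(self.club_backswing_deg)
        phi_f = self.club_follow_ratio * phi
        # downswing: Phi - (Phi+Phi_f) * rc(s/Td); crosses zero (ball contact) at
        s_i = self.downswing_s * np.arccos((phi_f - phi) / (phi + phi_f)) / np.pi
        omega_peak = np.pi * (phi + phi_f) / (2.0 * self.downswing_s)
        radius = self.gcv_mps / omega_peak
        return phi, phi_f, float(s_i), float(radius)

    @property
    def t_contact(self) -> float:
        """Time the club arc crosses its setup angle (ball position)."""
        return self.t_top + self._club_geometry()[2]

    @property
    def t_impact(self) -> float:
        """Centre of the deceleration spike == peak acceleration instant."""
        return self.t_contact + 0.5 * self.impact_stop_s

    @property
    def duration(self) -> float:
        return self.t_contact + self.impact_stop_s + TAIL_S

    def _segment_angle(self, t: np.ndarray, amplitude: float,
                       t_start: float, t_peak: float) -> np.ndarray:
        """Raised-cosine segment rotation (deg): 0 -> A -> -follow_ratio*A."""
        out = np.zeros_like(t)
        bs = (t >= t_start) & (t <= t_peak)
        out[bs] = amplitude * _raised_cosine((t[bs] - t_start) / (t_peak - t_start))
        t_end = t_peak + self.downswing_s
        ds = (t > t_peak) & (t <= t_end)
        drop = (1.0 + self.follow_ratio) * amplitude
        out[ds] = amplitude - drop * _raised_cosine((t[ds] - t_peak) / self.downswing_s)
        out[t > t_end] = amplitude - drop
        return out

    def pelvis_angle(self, t: np.ndarray) -> np.ndarray:
        return self._segment_angle(
            np.asarray(t, dtype=float), self.pmax_deg,
            self.t_thorax_start + self.pelvis_onset_lag_s,
            self.t_top - self.transition_lead_s,
        )

    def thorax_angle(self, t: np.ndarray) -> np.ndarray:
        return self._segment_angle(
            np.asarray(t, dtype=float), self.tmax_deg,
            self.t_thorax_start, self.t_top,
        )

    def club_angle(self, t: np.ndarray) -> np.ndarray:
        """Club arc angle (rad) relative to setup, including the stop window."""
        t = np.asarray(t, dtype=float)
        phi, phi_f, s_i, _ = self._club_geometry()
        t0, ttop, tc = self.t_thorax_start, self.t_top, self.t_top + s_i
        out = np.zeros_like(t)
        bs = (t >= t0) & (t <= ttop)
        out[bs] = phi * _raised_cosine((t[bs] - t0) / self.backswing_s)
        ds = (t > ttop) & (t <= tc)
        out[ds] = phi - (phi + phi_f) * _raised_cosine((t[ds] - ttop) / self.downswing_s)
        # deceleration window: speed falls as a raised cosine from v_c to 0
        v_c = -(phi + phi_f) * np.pi / (2 * self.downswing_s) * np.sin(np.pi * s_i
                                                                       / self.downswing_s)
        sw = (t > tc) & (t <= tc + self.impact_stop_s)
        u = (t[sw] - tc) / self.impact_stop_s
        out[sw] = v_c * self.impact_stop_s * (0.5 * u + np.sin(np.pi * u) / (2 * np.pi))
        out[t > tc + self.impact_stop_s] = v_c * self.impact_stop_s * 0.5
        return out

    def club_speed(self, t: np.ndarray) -> np.ndarray:
        """Analytic club-head speed (m/s)."""
        t = np.asarray(t, dtype=float)
        phi, phi_f, s_i, radius = self._club_geometry()
        t0, ttop, tc = self.t_thorax_start, self.t_top, self.t_top + s_i
        out = np.zeros_like(t)
        bs = (t >= t0) & (t <= ttop)
        out[bs] = (phi * np.pi / (2 * self.backswing_s)
                   * np.sin(np.pi * (t[bs] - t0) / self.backswing_s))
        ds = (t > ttop) & (t <= tc)
        out[ds] = ((phi + phi_f) * np.pi / (2 * self.downswing_s)
                   * np.sin(np.pi * (t[ds] - ttop) / self.downswing_s))
        v_c = ((phi + phi_f) * np.pi / (2 * self.downswing_s)
               * np.sin(np.pi * s_i / self.downswing_s))
        sw = (t > tc) & (t <= tc + self.impact_stop_s)
        u = (t[sw] - tc) / self.impact_stop_s
        out[sw] = v_c * 0.5 * (1.0 + np.cos(np.pi * u))
        return radius * out


@dataclass(frozen=True)
class GroundTruth:
    """Analytic events and parameter values for a generated trial."""

    events: SwingEvents
    parameters: SwingParameters
    profile: SwingProfile


@dataclass(frozen=True)
class SexPreset:
    """Between-player distribution of swing profiles for one sex."""

    sex: str
    pmax_mean: float
    pmax_sd: float
    tmax_mean: float
    tmax_sd: float
    gcv_mean: float
    gcv_sd: float
    pelvis_onset_lag_mean: float
    pelvis_onset_lag_sd: float
    transition_lead_mean: float
    transition_lead_sd: float
    backswing_mean: float
    backswing_sd: float
    downswing_mean: float
    downswing_sd: float

    def __post_init__(self) -> None:
        sds = (self.pmax_sd, self.tmax_sd, self.gcv_sd, self.pelvis_onset_lag_sd,
               self.transition_lead_sd, self.backswing_sd, self.downswing_sd)
        if any(sd < 0 for sd in sds):
            raise ValueError("preset SDs must be >= 0")


_PRESETS = {
    # Group means/SDs for Pmax, Tmax, GCV are the junior-elite study values
    # (8 girls, 6 boys). Timing presets are simulator choices: the 40 ms male
    # onset lag encodes the thorax-led backswing in boys; the 10 ms transition
    # lead yields the ~0.1 deg X-factor stretch both groups showed.
    "F": SexPreset(
        sex="F",
        pmax_mean=46.80, pmax_sd=6.44,
        tmax_mean=110.57, tmax_sd=7.21,
        gcv_mean=23.01, gcv_sd=1.34,
        pelvis_onset_lag_mean=0.0, pelvis_onset_lag_sd=0.010,
        transition_lead_mean=0.010, transition_lead_sd=0.003,
        backswing_mean=0.80, backswing_sd=0.05,
        downswing_mean=0.35, downswing_sd=0.02,
    ),
    "M": SexPreset(
        sex="M",
        pmax_mean=38.96, pmax_sd=8.44,
        tmax_mean=111.34, tmax_sd=17.51,
        gcv_mean=27.31, gcv_sd=1.99,
        pelvis_onset_lag_mean=0.040, pelvis_onset_lag_sd=0.010,
        transition_lead_mean=0.010, transition_lead_sd=0.003,
        backswing_mean=0.80, backswing_sd=0.05,
        downswing_mean=0.35, downswing_sd=0.02,
    ),
}


def sex_preset(sex: str) -> SexPreset:
    """Return the between-player profile distribution for ``sex`` (F or M)."""
    try:
        return _PRESETS[sex]
    except KeyError:
        raise ValueError(f"unknown sex category {sex!r}; expected 'F' or 'M'")


def _rotate_z(points: np.ndarray, theta_rad: np.ndarray) -> np.ndarray:
    """Rotate (k, 3) setup points about the vertical axis per-frame."""
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    out = np.empty((len(theta_rad), len(points), 3))
    out[:, :, 0] = np.outer(c, x) - np.outer(s, y)
    out[:, :, 1] = np.outer(s, x) + np.outer(c, y)
    out[:, :, 2] = z
    return out


def generate_trial(
    profile: SwingProfile,
    participant_id: str = "SYN",
    trial_index: int = 1,
    seed: int | None = None,
) -> tuple[TrialRecording, GroundTruth]:
    """Generate one trial and its analytic ground truth.

    A seed is mandatory: every generated artifact must be reproducible.
    """
    if seed is None:
        raise ValueError("seed is required (reproducibility is mandatory)")
    rng = np.random.default_rng(seed)
    fs = profile.sample_rate
    n = int(round(profile.duration * fs)) + 1
    t = np.arange(n) / fs

    theta_p = np.radians(profile.pelvis_angle(t))
    theta_t = np.radians(profile.thorax_angle(t))
    phi = profile.club_angle(t)
    _, _, _, radius = profile._club_geometry()

    pelvis_setup = np.array([
        [+PELVIS_HALF_WIDTH, +ASIS_ANTERIOR, PELVIS_HEIGHT],   # LASIS
        [-PELVIS_HALF_WIDTH, +ASIS_ANTERIOR, PELVIS_HEIGHT],   # RASIS
        [+PELVIS_HALF_WIDTH, -ASIS_ANTERIOR, PELVIS_HEIGHT],   # LPSIS
        [-PELVIS_HALF_WIDTH, -ASIS_ANTERIOR, PELVIS_HEIGHT],   # RPSIS
    ])
    thorax_setup = np.array([
        [+SHOULDER_HALF_WIDTH, 0.0, SHOULDER_HEIGHT],          # LACR
        [-SHOULDER_HALF_WIDTH, 0.0, SHOULDER_HEIGHT],          # RACR
    ])
    pelvis_pts = _rotate_z(pelvis_setup, theta_p)
    thorax_pts = _rotate_z(thorax_setup, theta_t)

    ax, ay = CLUB_AXIS_XY
    alpha = np.pi / 2 + phi  # head starts in front of the golfer, at the ball
    head = np.column_stack([
        ax + radius * np.cos(alpha),
        ay + radius * np.sin(alpha),
        np.full(n, CLUB_HEAD_HEIGHT),
    ])
    grip = np.column_stack([
        ax + GRIP_RADIUS_FRACTION * radius * np.cos(alpha),
        ay + GRIP_RADIUS_FRACTION * radius * np.sin(alpha),
        np.full(n, CLUB_GRIP_HEIGHT),
    ])

    markers = {
        "LASIS": pelvis_pts[:, 0], "RASIS": pelvis_pts[:, 1],
        "LPSIS": pelvis_pts[:, 2], "RPSIS": pelvis_pts[:, 3],
        "LACR": thorax_pts[:, 0], "RACR": thorax_pts[:, 1],
        "CLUB_GRIP": grip, "CLUB_HEAD": head,
    }
    if profile.noise_sd_m > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, profile.noise_sd_m, size=(n, 3))

    trial = TrialRecording(
        participant_id=participant_id,
        trial_index=trial_index,
        sample_rate=fs,
        markers=markers,
    )

    # analytic ground truth on the sampled grid
    speeds = profile.club_speed(t)
    start = int(np.flatnonzero(speeds >= 0.2)[0])
    top = int(round(profile.t_top * fs))
    impact = int(round(profile.t_impact * fs))
    events = SwingEvents(start_frame=start, top_frame=top, impact_frame=impact)

    t_start, t_top = start / fs, top / fs
    pe = profile.pelvis_angle
    th = profile.thorax_angle
    dense = np.linspace(t_top, impact / fs, 2001)
    sep = th(dense) - pe(dense)
    xfac = float(th(np.array([t_top]))[0] - pe(np.array([t_top]))[0])
    params = SwingParameters(
        tmax_deg=float(abs(th(np.array([t_top]))[0] - th(np.array([t_start]))[0])),
        pmax_deg=float(abs(pe(np.array([t_top]))[0] - pe(np.array([t_start]))[0])),
        xfac_deg=xfac,
        sxfac_deg=max(0.0, float(sep.max() - xfac)),
        gcv_mps=float(profile.gcv_mps),
        participant_id=participant_id,
        trial_index=trial_index,
    )
    return trial, GroundTruth(events=events, parameters=params, profile=profile)


def _draw_profile(preset: SexPreset, rng: np.random.Generator,
                  noise_sd_m: float) -> SwingProfile:
    def draw(mean: float, sd: float, lo: float) -> float:
        return float(max(lo, rng.normal(mean, sd)))

    return SwingProfile(
        pmax_deg=draw(preset.pmax_mean, preset.pmax_sd, 1.0),
        tmax_deg=draw(preset.tmax_mean, preset.tmax_sd, 1.0),
        gcv_mps=draw(preset.gcv_mean, preset.gcv_sd, 1.0),
        pelvis_onset_lag_s=float(rng.normal(preset.pelvis_onset_lag_mean,
                                            preset.pelvis_onset_lag_sd)),
        transition_lead_s=draw(preset.transition_lead_mean,
                               preset.transition_lead_sd, 0.0),
        backswing_s=draw(preset.backswing_mean, preset.backswing_sd, 0.3),
        downswing_s=draw(preset.downswing_mean, preset.downswing_sd, 0.15),
        noise_sd_m=noise_sd_m,
    )


def _jitter_profile(base: SwingProfile, preset: SexPreset,
                    rng: np.random.Generator,
                    jitter_fraction: float) -> SwingProfile:
    """Within-player trial-to-trial variation at a fraction of between-player SD."""
    j = jitter_fraction

    def jit(value: float, sd: float, lo: float) -> float:
        return float(max(lo, value + rng.normal(0.0, j * sd)))

    return replace(
        base,
        pmax_deg=jit(base.pmax_deg, preset.pmax_sd, 1.0),
        tmax_deg=jit(base.tmax_deg, preset.tmax_sd, 1.0),
        gcv_mps=jit(base.gcv_mps, preset.gcv_sd, 1.0),
        pelvis_onset_lag_s=float(base.pelvis_onset_lag_s
                                 + rng.normal(0.0, j * preset.pelvis_onset_lag_sd)),
        transition_lead_s=jit(base.transition_lead_s,
                              preset.transition_lead_sd, 0.0),
        backswing_s=jit(base.backswing_s, preset.backswing_sd, 0.3),
        downswing_s=jit(base.downswing_s, preset.downswing_sd, 0.15),
    )


def generate_cohort(
    n_female: int,
    n_male: int,
    trials_per_player: int = 10,
    seed: int | None = None,
    *,
    noise_sd_m: float = 0.002,
    jitter_fraction: float = 0.2,
) -> tuple[Cohort, pd.DataFrame]:
    """Generate a full cohort plus its ground-truth table.

    Player-level profiles are seeded normal draws from the sex presets
    (amplitudes truncated at zero); trial-to-trial jitter within a player is
    ``jitter_fraction`` of the between-player SD. Returns the cohort and a
    DataFrame with one row per trial holding the generating profile, the
    analytic events, and the analytic parameter values.
    """
    if min(n_female, n_male) < 1 or trials_per_player < 1:
        raise ValueError("counts must be >= 1")
    if seed is None:
        raise ValueError("seed is required (reproducibility is mandatory)")
    rng = np.random.default_rng(seed)
    participants: list[Participant] = []
    trials: list[TrialRecording] = []
    rows: list[dict] = []
    roster = [("F", i + 1) for i in range(n_female)] + \
             [("M", i + 1) for i in range(n_male)]
    for sex, num in roster:
        pid = f"{sex}{num:02d}"
        participants.append(Participant(participant_id=pid, sex=sex))
        preset = sex_preset(sex)
        base = _draw_profile(preset, rng, noise_sd_m)
        for k in range(1, trials_per_player + 1):
            prof = _jitter_profile(base, preset, rng, jitter_fraction)
            trial_seed = int(rng.integers(2 ** 31))
            trial, truth = generate_trial(prof, pid, k, seed=trial_seed)
            trials.append(trial)
            rows.append({
                "participant_id": pid,
                "trial_index": k,
                "sex": sex,
                "true_pmax_deg": truth.parameters.pmax_deg,
                "true_tmax_deg": truth.parameters.tmax_deg,
                "true_xfac_deg": truth.parameters.xfac_deg,
                "true_sxfac_deg": truth.parameters.sxfac_deg,
                "true_gcv_mps": truth.parameters.gcv_mps,
                "start_frame": truth.events.start_frame,
                "top_frame": truth.events.top_frame,
                "impact_frame": truth.events.impact_frame,
                "pelvis_onset_lag_s": prof.pelvis_onset_lag_s,
                "transition_lead_s": prof.transition_lead_s,
                "backswing_s": prof.backswing_s,
                "downswing_s": prof.downswing_s,
                "noise_sd_m": prof.noise_sd_m,
            })
    cohort = Cohort(participants=participants, trials=trials)
    return cohort, pd.DataFrame(rows)
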