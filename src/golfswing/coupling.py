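"""Pelvis-thorax continuous relative phase via the centered Hilbert transform.

The instantaneous phase of each segment's rotation angle is taken from the
analytic signal of the mean-centred series; the continuous relative phase
(CRP) is the pelvis phase minus the thorax phase, so a negative CRP means
the pelvis lags the thorax in phase space. (The display convention in which
"negative" means the pelvis *led* is available through an explicit
``negate`` flag rather than being applied silently.)

Because the Hilbert transform of a finite, non-periodic segment suffers
from edge (Gibbs) artifacts, the analysis window is mirror-padded before
the transform and the padding is discarded afterwards, confining the
artifact to the outer samples.

Each trial's CRP is aligned around the frame of maximal pelvis rotation and
linearly time-normalized to 200 samples: the portion up to that frame fills
the first half of the output nodes, the remainder fills the second half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .kinematics import AngleSeries, SwingEvents

N_NODES = 200


class PhaseUndefinedError(ValueError):
    """Constant (or too-short) signal: instantaneous phase is undefined."""


@dataclass
class CRPCurve:
    """A 200-sample normalized pelvis-thorax CRP curve for one trial."""

    values: np.ndarray
    align_node: int
    participant_id: str | None = None
    trial_index: int | None = None
    sign_convention: str = "pelvis_minus_thorax"
    align_fraction: float = 0.5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_NODES,):
            raise ValueError(f"CRP curve must have {N_NODES} samples, "
                             f"got {self.values.shape}")
        if not (0 <= self.align_node < N_NODES):
            raise ValueError(f"align_node out of range: {self.align_node}")
        if not np.isfinite(self.values).all():
            raise ValueError("CRP curve contains non-finite values")


def centered_hilbert_phase(x: np.ndarray, *, pad_fraction: float = 0.5) -> np.ndarray:
    """Unwrapped instantaneous phase (degrees) of a real series.

    The series is mean-centred, mirror-padded by ``pad_fraction`` of its
    length on each side, transformed, and the padding discarded.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 16:
        raise ValueError(f"need a 1-D signal of length >= 16, got {x.shape}")
    if np.ptp(x) == 0 or np.std(x) < 1e-12 * max(1.0, abs(x[0])):
        raise PhaseUndefinedError("phase undefined for a constant signal")
    n = len(x)
    centred = x - x.mean()
    pad = int(round(pad_fraction * n))
    padded = np.pad(centred, pad, mode="reflect") if pad > 0 else centred
    analytic = hilbert(padded)
    phase = np.unwrap(np.angle(analytic))
    if pad > 0:
        phase = phase[pad:pad + n]
    return np.degrees(phase)


def crp_series(
    pelvis_angle: np.ndarray,
    thorax_angle: np.ndarray,
    *,
    negate: bool = False,
    pad_fraction: float = 0.5,
) -> np.ndarray:
    """CRP(t) = phase(pelvis) - phase(thorax), in degrees.

    No wrapping is applied after subtracting the unwrapped phases.
    ``negate=True`` flips the sign to the display convention in which a
    negative CRP means the pelvis led the thorax.
    """
    pelvis_angle = np.asarray(pelvis_angle, dtype=float)
    thorax_angle = np.asarray(thorax_angle, dtype=float)
    if pelvis_angle.shape != thorax_angle.shape:
        raise ValueError("pelvis and thorax series must have equal length")
    crp = (centered_hilbert_phase(pelvis_angle, pad_fraction=pad_fraction)
           - centered_hilbert_phase(thorax_angle, pad_fraction=pad_fraction))
    # the two phases are unwrapped independently, so their difference carries
    # an arbitrary whole-turn branch offset; fold that single constant out
    # (no pointwise wrapping is applied)
    crp -= 360.0 * np.round(np.median(crp) / 360.0)
    return -crp if negate else crp


def _resample_linear(y: np.ndarray, n_out: int) -> np.ndarray:
    """Linear resampling preserving both endpoint values exactly."""
    src = np.linspace(0.0, 1.0, len(y))
    dst = np.linspace(0.0, 1.0, n_out)
    return np.interp(dst, src, y)


def align_and_normalize(
    series: np.ndarray,
    pelvis_angle: np.ndarray,
    events: SwingEvents,
    *,
    n_out: int = N_NODES,
    align_fraction: float = 0.5,
    strategy: str = "split",
    participant_id: str | None = None,
    trial_index: int | None = None,
    sign_convention: str = "pelvis_minus_thorax",
) -> CRPCurve:
    """Align a per-trial series around maximal pelvis rotation; resample.

    ``series`` and ``pelvis_angle`` are indexed on the trial's frame base;
    only the window ``[start_frame, impact_frame]`` is consumed. With the
    default ``split`` strategy the sub-segment up to the pelvis maximum is
    resampled to ``round(align_fraction * n_out)`` nodes and the remainder
    fills the rest, so the maximum always lands on the same output node.
    The ``shift`` strategy resamples the whole window and shifts it
    (edge-value padded) so the maximum lands on that node.
    """
    series = np.asarray(series, dtype=float)
    pelvis_angle = np.asarray(pelvis_angle, dtype=float)
    if series.shape != pelvis_angle.shape:
        raise ValueError("series and pelvis_angle must share the time base")
    s, i = events.start_frame, events.impact_frame
    window = series[s:i + 1]
    pelvis_win = pelvis_angle[s:i + 1]
    m = int(np.argmax(pelvis_win))
    if m == 0 or m == len(pelvis_win) - 1:
        raise ValueError("pelvis rotation has no interior maximum in "
                         "[start, impact]; cannot align")
    k = int(round(align_fraction * n_out))
    if not (1 < k < n_out):
        raise ValueError(f"align_fraction {align_fraction} leaves an empty segment")
    if strategy == "split":
        first = _resample_linear(window[:m + 1], k)
        second = _resample_linear(window[m:], n_out - k + 1)
        values = np.concatenate([first, second[1:]])
    elif strategy == "shift":
        values = _resample_linear(window, n_out)
        m_node = int(round(m / (len(window) - 1) * (n_out - 1)))
        shift = (k - 1) - m_node
        if shift > 0:
            values = np.concatenate([np.full(shift, values[0]), values[:-shift]])
        elif shift < 0:
            values = np.concatenate([values[-shift:], np.full(-shift, values[-1])])
    else:
        raise ValueError(f"unknown align strategy {strategy!r}")
    return CRPCurve(
        values=values,
        align_node=k - 1,
        participant_id=participant_id,
        trial_index=trial_index,
        sign_convention=sign_convention,
        align_fraction=align_fraction,
    )


def trial_crp_curve(
    angles: AngleSeries,
    events: SwingEvents,
    *,
    negate: bool = False,
    pad_fraction: float = 0.5,
    align_fraction: float = 0.5,
    strategy: str = "split",
    participant_id: str | None = None,
    trial_index: int | None = None,
) -> CRPCurve:
    """Full per-trial CRP: phase over [start, impact], aligned, normalized.

    Centering and phase estimation use the analysis interval
    ``[start_frame, impact_frame]`` only.
    """
    s, i = events.start_frame, events.impact_frame
    crp_win = crp_series(
        angles.pelvis_deg[s:i + 1], angles.thorax_deg[s:i + 1],
        negate=negate, pad_fraction=pad_fraction,
    )
    full = np.full(len(angles.pelvis_deg), np.nan)
    full[s:i + 1] = crp_win
    return align_and_normalize(
        full, angles.pelvis_deg, events,
        align_fraction=align_fraction, strategy=strategy,
        participant_id=participant_id, trial_index=trial_index,
        sign_convention=("thorax_minus_pelvis" if negate
                         else "pelvis_minus_thorax"),
    )
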