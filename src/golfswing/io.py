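"""Reading and writing trial marker data, cohort metadata, and result artifacts.

Trial files are plain CSV with a ``frame`` and ``time`` column plus
``<MARKER>_x/_y/_z`` columns for the eight required markers, in metres, in a
lab frame whose X axis is the target line and whose Z axis is vertical.
Cohorts pair a directory of ``{participant_id}_{trial_index}.csv`` files with
a metadata CSV (``participant_id,sex`` plus optional anthropometrics).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Required marker names: pelvis (anterior/posterior superior iliac spines,
#: both sides), thorax (both acromia), and the two club-shaft markers.
MARKER_NAMES = (
    "LASIS", "RASIS", "LPSIS", "RPSIS",
    "LACR", "RACR", "CLUB_GRIP", "CLUB_HEAD",
)

SEX_CATEGORIES = ("F", "M")


class FormatError(ValueError):
    """Malformed trial or metadata file (missing columns, bad values)."""


class DataQualityError(ValueError):
    """File parsed but its content fails quality rules (gaps, duplicates)."""


@dataclass
class TrialRecording:
    """One swing's marker trajectories at a fixed sample rate.

    ``markers`` maps each name in :data:`MARKER_NAMES` to an ``(n, 3)`` float
    array of positions in metres. All markers share the same frame count.
    """

    participant_id: str
    trial_index: int
    sample_rate: float
    markers: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.trial_index < 1:
            raise ValueError(f"trial_index must be >= 1, got {self.trial_index}")
        missing = [m for m in MARKER_NAMES if m not in self.markers]
        if missing:
            raise FormatError(f"missing required markers: {missing}")
        arrays = {}
        lengths = set()
        for name in MARKER_NAMES:
            arr = np.asarray(self.markers[name], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"marker {name} must be (n, 3), got {arr.shape}")
            if not np.isfinite(arr).all():
                raise DataQualityError(f"marker {name} contains non-finite values")
            arrays[name] = arr
            lengths.add(arr.shape[0])
        if len(lengths) != 1:
            raise ValueError(f"markers have unequal lengths: {sorted(lengths)}")
        n = lengths.pop()
        if n < 2:
            raise ValueError(f"need at least 2 frames, got {n}")
        object.__setattr__(self, "markers", arrays)

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.sample_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sample_rate


@dataclass
class Participant:
    participant_id: str
    sex: str
    height_m: float | None = None
    mass_kg: float | None = None
    handicap: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEX_CATEGORIES:
            raise FormatError(
                f"participant {self.participant_id!r}: sex must be one of "
                f"{SEX_CATEGORIES}, got {self.sex!r}"
            )


@dataclass
class Cohort:
    """Participants plus their trials; every trial belongs to a participant."""

    participants: list[Participant]
    trials: list[TrialRecording] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate participant ids: {dupes}")
        known = set(ids)
        orphans = sorted({t.participant_id for t in self.trials} - known)
        if orphans:
            raise FormatError(f"trials reference unknown participants: {orphans}")
        seen: set[tuple[str, int]] = set()
        for t in self.trials:
            key = (t.participant_id, t.trial_index)
            if key in seen:
                raise DataQualityError(f"duplicate trial {key}")
            seen.add(key)

    def sex_of(self, participant_id: str) -> str:
        for p in self.participants:
            if p.participant_id == participant_id:
                return p.sex
        raise KeyError(participant_id)

    def trials_of(self, participant_id: str) -> list[TrialRecording]:
        return [t for t in self.trials if t.participant_id == participant_id]


def _interpolate_gaps(values: np.ndarray, marker: str, max_fraction: float) -> np.ndarray:
    """Linearly fill NaN runs in an (n, 3) trajectory; reject large gaps."""
    bad = ~np.isfinite(values).all(axis=1)
    if not bad.any():
        return values
    frac = bad.mean()
    if frac > max_fraction:
        raise DataQualityError(
            f"marker {marker}: {frac:.1%} of samples missing "
            f"(limit {max_fraction:.0%})"
        )
    if bad[0] or bad[-1]:
        raise DataQualityError(f"marker {marker}: missing samples at trial boundary")
    idx = np.arange(len(values))
    out = values.copy()
    for axis in range(3):
        col = out[:, axis]
        nan = ~np.isfinite(col)
        if nan.any():
            col[nan] = np.interp(idx[nan], idx[~nan], col[~nan])
    warnings.warn(
        f"marker {marker}: linearly interpolated {int(bad.sum())} missing samples",
        stacklevel=3,
    )
    return out


def read_trial(
    path: str | Path,
    *,
    participant_id: str | None = None,
    trial_index: int | None = None,
    sample_rate: float | None = None,
    millimetres: bool = False,
    max_gap_fraction: float = 0.1,
) -> TrialRecording:
    """Read one trial CSV into a :class:`TrialRecording`.

    The sample rate is inferred from the ``time`` column unless given
    explicitly. ``millimetres=True`` converts positions to metres on read.
    Gaps of at most ``max_gap_fraction`` per marker are linearly interpolated
    with a warning; larger gaps raise :class:`DataQualityError`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for marker in MARKER_NAMES:
        for axis in "xyz":
            col = f"{marker}_{axis}"
            if col not in df.columns:
                raise FormatError(f"{path.name}: missing column for marker {marker} ({col})")
    if sample_rate is None:
        if "time" not in df.columns:
            raise FormatError(f"{path.name}: no time column and no sample_rate given")
        t = df["time"].to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) == 0 or np.any(dt <= 0):
            raise FormatError(f"{path.name}: time column is not strictly increasing")
        sample_rate = 1.0 / float(np.median(dt))
    if participant_id is None or trial_index is None:
        m = re.match(r"(?P<pid>.+)_(?P<idx>\d+)$", path.stem)
        if m is None:
            raise FormatError(
                f"{path.name}: cannot parse participant_id/trial_index from filename"
            )
        participant_id = participant_id or m.group("pid")
        trial_index = trial_index or int(m.group("idx"))
    scale = 1e-3 if millimetres else 1.0
    markers = {}
    for marker in MARKER_NAMES:
        values = df[[f"{marker}_{a}" for a in "xyz"]].to_numpy(dtype=float) * scale
        markers[marker] = _interpolate_gaps(values, marker, max_gap_fraction)
    return TrialRecording(
        participant_id=participant_id,
        trial_index=trial_index,
        sample_rate=sample_rate,
        markers=markers,
    )


def write_trial(trial: TrialRecording, path: str | Path) -> Path:
    """Write a trial as CSV (inverse of :func:`read_trial`)."""
    path = Path(path)
    data: dict[str, np.ndarray] = {
        "frame": np.arange(trial.n_frames),
        "time": trial.times(),
    }
    for marker in MARKER_NAMES:
        for j, axis in enumerate("xyz"):
            data[f"{marker}_{axis}"] = trial.markers[marker][:, j]
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def read_metadata(path: str | Path) -> list[Participant]:
    df = pd.read_csv(path)
    for col in ("participant_id", "sex"):
        if col not in df.columns:
            raise FormatError(f"{Path(path).name}: missing column {col}")
    participants = []
    for _, row in df.iterrows():
        participants.append(
            Participant(
                participant_id=str(row["participant_id"]),
                sex=str(row["sex"]),
                height_m=float(row["height_m"]) if "height_m" in df.columns else None,
                mass_kg=float(row["mass_kg"]) if "mass_kg" in df.columns else None,
                handicap=float(row["handicap"]) if "handicap" in df.columns else None,
            )
        )
    return participants


def read_cohort(
    trial_dir: str | Path,
    metadata_path: str | Path,
    **trial_kwargs,
) -> Cohort:
    """Read all ``{pid}_{idx}.csv`` trials in a directory plus metadata."""
    trial_dir = Path(trial_dir)
    participants = read_metadata(metadata_path)
    known = {p.participant_id for p in participants}
    files = sorted(p for p in trial_dir.glob("*.csv") if re.match(r".+_\d+$", p.stem))
    if not files:
        raise FormatError(f"no trial files found in {trial_dir}")
    trials = []
    orphans = []
    for f in files:
        m = re.match(r"(?P<pid>.+)_(?P<idx>\d+)$", f.stem)
        assert m is not None
        if m.group("pid") not in known:
            orphans.append(f.stem)
            continue
        trials.append(read_trial(f, **trial_kwargs))
    if orphans:
        raise FormatError(f"trial files without metadata entry: {orphans}")
    return Cohort(participants=participants, trials=trials)


# ---------------------------------------------------------------------------
# Result artifacts
# ---------------------------------------------------------------------------

def _params_frame(parameters: Sequence) -> pd.DataFrame:
    rows = []
    for p in parameters:
        rows.append(
            {
                "participant_id": p.participant_id,
                "trial_index": p.trial_index,
                "tmax_deg": p.tmax_deg,
                "pmax_deg": p.pmax_deg,
                "xfac_deg": p.xfac_deg,
                "sxfac_deg": p.sxfac_deg,
                "gcv_mps": p.gcv_mps,
            }
        )
    return pd.DataFrame(rows)


def _crp_frame(curves: Sequence) -> pd.DataFrame:
    rows = []
    for c in curves:
        row = {
            "participant_id": c.participant_id,
            "trial_index": c.trial_index,
            "align_node": c.align_node,
            "sign_convention": c.sign_convention,
        }
        row.update({f"node_{i:03d}": v for i, v in enumerate(c.values)})
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(parameters, crp, spm, stats, out_dir: str | Path) -> dict[str, Path]:
    """Write per-trial parameters, CRP curves, SPM and group stats to disk.

    Returns the mapping of artifact name to written path. Floats are written
    at full ``repr`` precision so a read-back is value-identical.
    """
    if not parameters:
        raise ValueError("no parameters to write; refusing to emit empty results")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "parameters": out_dir / "parameters.csv",
        "crp": out_dir / "crp_curves.csv",
        "spm": out_dir / "spm.json",
        "stats": out_dir / "stats.json",
    }
    _params_frame(parameters).to_csv(paths["parameters"], index=False)
    _crp_frame(crp).to_csv(paths["crp"], index=False)
    with open(paths["spm"], "w") as fh:
        json.dump(spm.to_dict() if hasattr(spm, "to_dict") else spm, fh, indent=1,
                  sort_keys=True)
    with open(paths["stats"], "w") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True)
    return paths


def read_results(out_dir: str | Path) -> dict:
    """Read back the artifact set written by :func:`write_results`."""
    out_dir = Path(out_dir)
    out = {
        "parameters": pd.read_csv(out_dir / "parameters.csv"),
        "crp": pd.read_csv(out_dir / "crp_curves.csv"),
    }
    with open(out_dir / "spm.json") as fh:
        out["spm"] = json.load(fh)
    with open(out_dir / "stats.json") as fh:
        out["stats"] = json.load(fh)
    return out
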