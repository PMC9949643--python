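"""Trial data model and plain-text I/O.

A trial couples one participant's tap onsets with the metronome tick
schedule they tapped against, plus the metadata the downstream analysis
needs (tempo, language group, trial index).  All times are float seconds
from trial start; tempo is stored as integer beats per minute.

Trial files are CSV with a one-line JSON header (prefixed ``# ``) so each
trial is self-describing; a cohort is a manifest CSV pointing at trial
files.  Serialization preserves times to better than 1e-9 s and metadata
exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Metronome tempi used in the study: 80-140 bpm in 10-bpm steps.
VALID_TEMPI = (80, 90, 100, 110, 120, 130, 140)

LANGUAGE_GROUPS = ("monolingual", "multilingual")

#: Trials last at most two minutes.
MAX_TRIAL_DURATION_S = 120.0

_TIME_FMT = "{:.9f}"


class TrialFormatError(ValueError):
    """A trial or manifest file violates the expected format."""


def _as_time_array(values: Sequence[float], name: str) -> np.ndarray:
    """Coerce to a read-only, strictly increasing, non-negative 1-D float array."""
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size:
        if not np.all(np.isfinite(arr)):
            row = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise ValueError(f"{name}: non-finite time at row {row}")
        if arr[0] < 0:
            raise ValueError(f"{name}: negative time at row 0")
        bad = np.flatnonzero(np.diff(arr) <= 0)
        if bad.size:
            row = int(bad[0]) + 1
            raise ValueError(f"{name}: times not strictly increasing at row {row}")
    arr = arr.copy()
    arr.setflags(write=False)
    return arr


@dataclass(frozen=True)
class MetronomeTrack:
    """An isochronous tick schedule at a fixed tempo.

    Parameters
    ----------
    tempo_bpm : int
        Beats per minute; the interbeat interval is ``60 / tempo_bpm`` s.
    tick_times : array-like of float
        Strictly increasing tick onsets in seconds from trial start.
    """

    tempo_bpm: int
    tick_times: np.ndarray

    def __post_init__(self) -> None:
        if self.tempo_bpm <= 0:
            raise ValueError(f"tempo_bpm must be positive, got {self.tempo_bpm}")
        ticks = _as_time_array(self.tick_times, "tick_times")
        if ticks.size == 0:
            raise ValueError("a metronome track needs at least one tick")
        object.__setattr__(self, "tick_times", ticks)

    @property
    def interbeat_interval(self) -> float:
        """T, the metronome's interbeat interval in seconds (60 / bpm)."""
        return 60.0 / self.tempo_bpm

    def __len__(self) -> int:
        return int(self.tick_times.size)


@dataclass(frozen=True)
class TapSeries:
    """Participant tap onsets, seconds from trial start.

    May be empty: the study contained one trial in which the participant
    never tapped; such trials are representable but excluded downstream.
    """

    times: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.times, dtype=float)
        if arr.size == 0:
            arr = np.empty(0, dtype=float)
            arr.setflags(write=False)
        else:
            arr = _as_time_array(self.times, "tap_times")
        object.__setattr__(self, "times", arr)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def is_empty(self) -> bool:
        return self.times.size == 0


@dataclass(frozen=True)
class Trial:
    """One participant x tempo recording with metadata."""

    participant_id: str
    trial_index: int
    tempo_bpm: int
    language_group: str
    taps: TapSeries
    metronome: MetronomeTrack
    warning_time: Optional[float] = None

    def __post_init__(self) -> None:
        if not isinstance(self.taps, TapSeries):
            object.__setattr__(self, "taps", TapSeries(self.taps))
        if self.trial_index < 1:
            raise ValueError(f"trial_index must be >= 1, got {self.trial_index}")
        if self.language_group not in LANGUAGE_GROUPS:
            raise ValueError(
                f"language_group must be one of {LANGUAGE_GROUPS}, "
                f"got {self.language_group!r}"
            )
        if self.tempo_bpm != self.metronome.tempo_bpm:
            raise ValueError(
                f"trial tempo_bpm={self.tempo_bpm} does not match metronome "
                f"tempo_bpm={self.metronome.tempo_bpm}"
            )
        if self.duration > MAX_TRIAL_DURATION_S + 1e-6:
            raise ValueError(
                f"trial duration {self.duration:.3f}s exceeds the "
                f"{MAX_TRIAL_DURATION_S:.0f}s maximum"
            )

    @property
    def duration(self) -> float:
        """Last event time (tap or tick) in seconds."""
        last_tap = float(self.taps.times[-1]) if len(self.taps) else 0.0
        return max(last_tap, float(self.metronome.tick_times[-1]))


def build_metronome(
    tempo_bpm: int, duration_s: float, start_offset_s: float = 0.0
) -> MetronomeTrack:
    """Programmed metronome: ticks at ``start_offset_s + k*(60/tempo_bpm)``
    for k = 0, 1, ... while the tick time does not exceed ``duration_s``.
    """
    if tempo_bpm <= 0:
        raise ValueError(f"tempo_bpm must be positive, got {tempo_bpm}")
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    if start_offset_s < 0 or start_offset_s > duration_s:
        raise ValueError("start_offset_s must lie within [0, duration_s]")
    period = 60.0 / tempo_bpm
    # small slack so an exact final tick survives float division
    n_ticks = int(math.floor((duration_s - start_offset_s) / period + 1e-9)) + 1
    ticks = start_offset_s + np.arange(n_ticks) * period
    return MetronomeTrack(tempo_bpm=tempo_bpm, tick_times=ticks)


# ---------------------------------------------------------------------------
# trial file format: "# <json metadata>" line, then CSV event,time_s
# ---------------------------------------------------------------------------

_REQUIRED_META = ("participant_id", "trial_index", "tempo_bpm", "language_group")


def write_trial(trial: Trial, path: Path | str) -> Path:
    """Write a trial to a self-describing CSV file."""
    path = Path(path)
    meta = {
        "participant_id": trial.participant_id,
        "trial_index": int(trial.trial_index),
        "tempo_bpm": int(trial.tempo_bpm),
        "language_group": trial.language_group,
        "warning_time": (
            None if trial.warning_time is None else float(trial.warning_time)
        ),
    }
    events = [("tick", t) for t in trial.metronome.tick_times]
    events += [("tap", t) for t in trial.taps.times]
    events.sort(key=lambda e: (e[1], e[0]))
    lines = ["# " + json.dumps(meta, sort_keys=True), "event,time_s"]
    lines += [f"{ev},{_TIME_FMT.format(t)}" for ev, t in events]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_trial(path: Path | str) -> Trial:
    """Read a trial file written by :func:`write_trial`."""
    path = Path(path)
    if not path.exists():
        raise TrialFormatError(f"trial file does not exist: {path}")
    with path.open() as fh:
        first = fh.readline().strip()
    if not first.startswith("# "):
        raise TrialFormatError(f"{path}: missing '# <json>' metadata header line")
    try:
        meta = json.loads(first[2:])
    except json.JSONDecodeError as exc:
        raise TrialFormatError(f"{path}: malformed JSON metadata header: {exc}")
    for key in _REQUIRED_META:
        if key not in meta:
            raise TrialFormatError(f"{path}: metadata missing field {key!r}")

    table = pd.read_csv(path, comment="#")
    expected = {"event", "time_s"}
    if set(table.columns) != expected:
        unknown = sorted(set(table.columns) - expected)
        missing = sorted(expected - set(table.columns))
        raise TrialFormatError(
            f"{path}: bad columns (unknown={unknown}, missing={missing})"
        )
    bad = ~table["event"].isin(["tap", "tick"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TrialFormatError(
            f"{path}: unknown event {table['event'].iloc[row]!r} at data row {row}"
        )
    taps = table.loc[table["event"] == "tap", "time_s"].to_numpy(dtype=float)
    ticks = table.loc[table["event"] == "tick", "time_s"].to_numpy(dtype=float)
    try:
        trial = Trial(
            participant_id=str(meta["participant_id"]),
            trial_index=int(meta["trial_index"]),
            tempo_bpm=int(meta["tempo_bpm"]),
            language_group=str(meta["language_group"]),
            taps=TapSeries(taps),
            metronome=MetronomeTrack(int(meta["tempo_bpm"]), ticks),
            warning_time=meta.get("warning_time"),
        )
    except ValueError as exc:
        raise TrialFormatError(f"{path}: {exc}")
    return trial


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("participant_id", "trial_index", "tempo_bpm", "language_group", "path")


def trial_filename(trial: Trial) -> str:
    return f"{trial.participant_id}_trial{trial.trial_index:02d}.csv"


def write_cohort(
    trials: Iterable[Trial],
    directory: Path | str,
    manifest_name: str = "manifest.csv",
) -> Path:
    """Write each trial plus a manifest CSV; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        fname = trial_filename(trial)
        write_trial(trial, directory / fname)
        rows.append(
            {
                "participant_id": trial.participant_id,
                "trial_index": trial.trial_index,
                "tempo_bpm": trial.tempo_bpm,
                "language_group": trial.language_group,
                "path": fname,
            }
        )
    manifest = directory / manifest_name
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


def read_manifest(path: Path | str) -> list[Trial]:
    """Load every trial referenced by a manifest, in manifest order."""
    path = Path(path)
    if not path.exists():
        raise TrialFormatError(f"manifest does not exist: {path}")
    table = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise TrialFormatError(f"{path}: manifest missing columns {sorted(missing)}")
    dup = table.duplicated(subset=["participant_id", "trial_index"])
    if dup.any():
        row = table.loc[dup].iloc[0]
        raise TrialFormatError(
            f"{path}: duplicate trial ({row['participant_id']}, "
            f"trial_index={row['trial_index']})"
        )
    dangling = [
        str(path.parent / p) for p in table["path"] if not (path.parent / p).exists()
    ]
    if dangling:
        raise TrialFormatError(f"{path}: dangling trial paths: {dangling}")

    trials = []
    for _, row in table.iterrows():
        trial = read_trial(path.parent / row["path"])
        for key in ("participant_id", "trial_index", "tempo_bpm", "language_group"):
            if str(getattr(trial, key)) != str(row[key]):
                raise TrialFormatError(
                    f"{path}: manifest/{row['path']} disagree on {key} "
                    f"({row[key]!r} vs {getattr(trial, key)!r})"
                )
        trials.append(trial)
    return trials
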