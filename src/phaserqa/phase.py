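"""Circular relative phase between taps and metronome ticks.

The phasing relationship of a tap to the metronome is the relative phase

    psi = -2 * pi * dt / T

where ``dt`` is the signed offset of the tap from its *nearest* tick and
``T`` the metronome's interbeat interval.  The sign convention makes psi
positive when the participant taps ahead of (earlier than) the tick, so a
tapper running slightly fast accumulates positive phase and eventually
"laps" the metronome: one full 2*pi traversal is one phasing round.

This module wraps psi onto [0, 2*pi), decomposes it into unit-circle
coordinates (cos psi, sin psi) for circular-safe recurrence analysis,
unwraps it into a continuous trajectory, counts completed laps, classifies
trials by lap count, assigns taps to phase regions, and bins tempo.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .trials import MetronomeTrack, Trial

TWO_PI = 2.0 * np.pi

TrialLabel = Literal["successful", "unsuccessful", "incomplete"]

#: Region boundaries in radians: sync < 45deg or >= 315deg, then three
#: half-open 90deg sectors r1/r2/r3 centred on 90/180/270deg.
REGION_BOUNDS_RAD = tuple(np.deg2rad([45.0, 135.0, 225.0, 315.0]))

#: Study tempo bins (bpm -> categorical level).
TEMPO_BINS = {
    80: "lower",
    90: "lower",
    100: "middle",
    110: "middle",
    120: "middle",
    130: "upper",
    140: "upper",
}


class EmptyTrialError(ValueError):
    """Raised for trials with no taps: excluded, mirroring the study's
    removal of the one trial in which the participant never tapped."""


@dataclass(frozen=True)
class PhaseSeries:
    """Per-tap relative phase of one trial.

    Attributes
    ----------
    tap_times : array of float, seconds
    dt : array of float
        Signed offset to the nearest tick, seconds; ``|dt| <= T/2``.
    psi_raw : array of float
        ``-2*pi*dt/T`` in radians (positive = tapping ahead).
    psi_wrapped : array of float
        psi_raw wrapped onto [0, 2*pi).
    psi_unwrapped : array of float
        Continuous phase trajectory (minimal-step unwrapping).
    x, y : arrays of float
        cos/sin of the wrapped phase; the 2-D signal analysed by MdRQA.
    interbeat_interval : float
        T in seconds.
    """

    tap_times: np.ndarray
    dt: np.ndarray
    psi_raw: np.ndarray
    psi_wrapped: np.ndarray
    psi_unwrapped: np.ndarray
    x: np.ndarray
    y: np.ndarray
    interbeat_interval: float

    def __len__(self) -> int:
        return int(self.tap_times.size)

    def to_frame(self, regions: Optional[np.ndarray] = None) -> pd.DataFrame:
        """Export as a tidy table (CSV-ready)."""
        out = pd.DataFrame(
            {
                "tap_time_s": self.tap_times,
                "dt_s": self.dt,
                "psi_rad": self.psi_raw,
                "psi_wrapped_rad": self.psi_wrapped,
                "psi_unwrapped_rad": self.psi_unwrapped,
                "x": self.x,
                "y": self.y,
            }
        )
        out["region"] = assign_regions(self.psi_wrapped) if regions is None else regions
        return out


@dataclass(frozen=True)
class TrialClassification:
    """Lap count plus the trial-type label it implies.

    successful <=> exactly one lap; unsuccessful <=> two or more;
    incomplete <=> zero.
    """

    lap_count: int
    label: TrialLabel

    def __post_init__(self) -> None:
        if self.lap_count < 0:
            raise ValueError("lap_count must be non-negative")
        if self.label != label_for_laps(self.lap_count):
            raise ValueError(
                f"label {self.label!r} inconsistent with lap_count={self.lap_count}"
            )


def label_for_laps(lap_count: int) -> TrialLabel:
    if lap_count == 0:
        return "incomplete"
    if lap_count == 1:
        return "successful"
    return "unsuccessful"


def wrap_phase(angle):
    """Wrap angle(s) in radians onto [0, 2*pi)."""
    arr = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("wrap_phase requires finite angles")
    wrapped = np.mod(arr, TWO_PI)
    # np.mod of a tiny negative can round up to exactly 2*pi
    wrapped = np.where(wrapped >= TWO_PI, 0.0, wrapped)
    return float(wrapped) if np.isscalar(angle) else wrapped


def _minimal_steps(diffs: np.ndarray) -> np.ndarray:
    """Map angle differences into (-pi, pi]."""
    return np.pi - np.mod(np.pi - diffs, TWO_PI)


def unwrap_phase(psi_wrapped: Sequence[float]) -> np.ndarray:
    """Minimal-step unwrapping: first value preserved, successive
    differences mapped into (-pi, pi], cumulative sum thereafter."""
    arr = np.asarray(psi_wrapped, dtype=float)
    if arr.size == 0:
        raise ValueError("unwrap_phase requires at least one value")
    if arr.size == 1:
        return arr.copy()
    steps = _minimal_steps(np.diff(arr))
    return arr[0] + np.concatenate(([0.0], np.cumsum(steps)))


def nearest_tick_offset(tap_times, metronome: MetronomeTrack) -> np.ndarray:
    """Signed offset of each tap from its nearest metronome tick.

    Equidistant taps (exactly halfway between two ticks) resolve to the
    *earlier* tick, giving dt = +T/2; deterministic and measure-zero.
    """
    taps = np.atleast_1d(np.asarray(tap_times, dtype=float))
    ticks = metronome.tick_times
    idx = np.searchsorted(ticks, taps)
    prev_idx = np.clip(idx - 1, 0, len(ticks) - 1)
    next_idx = np.clip(idx, 0, len(ticks) - 1)
    d_prev = taps - ticks[prev_idx]
    d_next = ticks[next_idx] - taps
    take_prev = (d_prev <= d_next) | (idx == len(ticks))
    take_prev &= idx > 0
    nearest = np.where(take_prev, ticks[prev_idx], ticks[next_idx])
    dt = taps - nearest
    if np.isscalar(tap_times) or np.ndim(tap_times) == 0:
        return float(dt[0])
    return dt


def relative_phase(trial: Trial) -> PhaseSeries:
    """Compute the full per-tap phase series of a trial."""
    if len(trial.taps) == 0:
        raise EmptyTrialError(
            f"trial ({trial.participant_id}, {trial.trial_index}) has no taps"
        )
    T = trial.metronome.interbeat_interval
    dt = nearest_tick_offset(trial.taps.times, trial.metronome)
    psi_raw = -TWO_PI * dt / T
    psi_wrapped = wrap_phase(psi_raw)
    psi_unwrapped = unwrap_phase(psi_wrapped)
    return PhaseSeries(
        tap_times=trial.taps.times,
        dt=dt,
        psi_raw=psi_raw,
        psi_wrapped=psi_wrapped,
        psi_unwrapped=psi_unwrapped,
        x=np.cos(psi_wrapped),
        y=np.sin(psi_wrapped),
        interbeat_interval=T,
    )


def count_laps(psi_unwrapped: Sequence[float], tol: float = 1e-9) -> int:
    """Completed phasing laps: floor of the maximum forward excursion of
    the unwrapped phase (relative to its start) in units of 2*pi.

    Only forward (positive) drift counts — phasing is performed by tapping
    ahead of the metronome.  ``tol`` absorbs float error when an excursion
    lands exactly on a multiple of 2*pi.
    """
    arr = np.asarray(psi_unwrapped, dtype=float)
    if arr.size == 0:
        raise ValueError("count_laps requires a non-empty series")
    excursion = max(0.0, float(np.max(arr - arr[0])))
    return int(np.floor((excursion + tol) / TWO_PI))


def classify_trial(trial: Trial) -> TrialClassification:
    """Classify a trial by its completed lap count."""
    series = relative_phase(trial)  # raises EmptyTrialError on zero taps
    laps = count_laps(series.psi_unwrapped)
    return TrialClassification(lap_count=laps, label=label_for_laps(laps))


def assign_regions(psi_wrapped) -> np.ndarray:
    """Assign each wrapped phase to a region label.

    r1: 45deg <= psi < 135deg; r2: 135deg <= psi < 225deg;
    r3: 225deg <= psi < 315deg; sync otherwise (psi < 45deg or >= 315deg).
    """
    arr = np.atleast_1d(np.asarray(psi_wrapped, dtype=float))
    if arr.size and (np.any(arr < 0) or np.any(arr >= TWO_PI)):
        raise ValueError("assign_regions requires phases in [0, 2*pi)")
    b1, b2, b3, b4 = REGION_BOUNDS_RAD
    labels = np.select(
        [(arr >= b1) & (arr < b2), (arr >= b2) & (arr < b3), (arr >= b3) & (arr < b4)],
        ["r1", "r2", "r3"],
        default="sync",
    )
    if np.isscalar(psi_wrapped) or np.ndim(psi_wrapped) == 0:
        return str(labels[0])
    return labels


def tempo_bin(tempo_bpm: int, bins: Optional[dict] = None) -> str:
    """Categorical tempo level: lower (80-90), middle (100-120),
    upper (130-140) bpm.  ``bins`` may override the mapping."""
    mapping = TEMPO_BINS if bins is None else bins
    try:
        return mapping[int(tempo_bpm)]
    except KeyError:
        raise ValueError(
            f"tempo {tempo_bpm} bpm is not a study tempo {sorted(mapping)}"
        ) from None
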