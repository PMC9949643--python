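"""Event-based simulator of human-metronome phasing trials.

The tapper is a first-order linear phase-correction oscillator: given tap
time ``t[k]`` with signed asynchrony ``A[k]`` to the nearest tick,

    t[k+1] = t[k] + T/(1 + delta[k]) - alpha[k] * A[k] + eps[k]

where ``T`` is the interbeat interval, ``delta`` the intended detuning
(the tapper's period is ``T/(1+delta)``), ``alpha`` the per-tap linear
correction gain toward the metronome, and ``eps`` Gaussian motor noise.

A trial has the study's structure: a synchronized lead-in, a warning
signal after which the tapper detunes (correction off, pure drift), and —
for trials meant to succeed — resynchronization after the first completed
lap (detune off, correction on, a few lead-out beats, stop).  With
correction on and no detuning the asynchrony is mean-reverting, so phase
never laps; with detuning and no correction the phase drifts forward at
exactly ``2*pi*delta/(1+delta)`` per tap.

Every trial carries its ground truth (lap count, label, true unwrapped
phase), so classification and region analyses can be tested against known
answers.  All randomness flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .phase import TWO_PI, count_laps, label_for_laps, nearest_tick_offset
from .trials import (
    MetronomeTrack,
    TapSeries,
    Trial,
    VALID_TEMPI,
    build_metronome,
    write_cohort,
)

#: Trial-type mix observed in the study: 38% successful, 41% unsuccessful,
#: 21% incomplete.
DEFAULT_ARCHETYPE_MIX = {"successful": 0.38, "unsuccessful": 0.41, "incomplete": 0.21}

#: Minimum spacing enforced between consecutive taps (s).
_MIN_TAP_GAP = 1e-3


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated phasing trial.

    detune_ratio is the fractional tempo increase while phasing: the
    tapper's intended period is ``T/(1+detune_ratio)``.  The default 0.05
    (tapping 5% fast) laps the metronome in ~21 taps, a deliberate pace a
    person can hold.  correction_gain in [0, 2) is the stable range of
    linear phase correction; 0.3 is a typical human value.  motor_noise_sd
    is per-tap Gaussian timing noise in seconds (human tap jitter is
    roughly 0.01-0.02 s).
    """

    tempo_bpm: int = 110
    duration_s: float = 120.0
    lead_in_beats: int = 8
    detune_ratio: float = 0.05
    correction_gain: float = 0.3
    motor_noise_sd: float = 0.0
    resync_stop: bool = True
    lead_out_beats: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tempo_bpm <= 0:
            raise ValueError("tempo_bpm must be positive")
        if not (0 < self.duration_s <= 120.0):
            raise ValueError("duration_s must lie in (0, 120]")
        if self.lead_in_beats < 1:
            raise ValueError("lead_in_beats must be >= 1")
        if self.detune_ratio < 0:
            raise ValueError("detune_ratio must be >= 0")
        if not (0 <= self.correction_gain < 2):
            raise ValueError(
                "correction_gain must lie in [0, 2): the linear correction "
                "map is unstable at alpha >= 2"
            )
        if self.motor_noise_sd < 0:
            raise ValueError("motor_noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator knows about the trial it generated."""

    lap_count: int
    label: str
    psi_true_unwrapped: np.ndarray
    warning_time: float


#: Archetype presets: config overrides producing the three trial types.
ARCHETYPE_PRESETS: Dict[str, dict] = {
    # detune, lap once, resynchronize
    "successful": {"detune_ratio": 0.05, "resync_stop": True},
    # detune and never resynchronize: laps repeatedly for the whole trial
    "unsuccessful": {"detune_ratio": 0.05, "resync_stop": False},
    # never detunes: correction keeps it locked in-phase, zero laps
    "incomplete": {"detune_ratio": 0.0, "resync_stop": False},
}


def archetype_config(
    name: str, tempo_bpm: int = 110, seed: int = 0, **overrides
) -> SimulationConfig:
    """Build a SimulationConfig for a named archetype."""
    if name not in ARCHETYPE_PRESETS:
        raise ValueError(
            f"unknown archetype {name!r}; choose from {sorted(ARCHETYPE_PRESETS)}"
        )
    kwargs = dict(ARCHETYPE_PRESETS[name])
    kwargs.update(overrides)
    return SimulationConfig(tempo_bpm=tempo_bpm, seed=seed, **kwargs)


def simulate_trial(
    config: SimulationConfig,
    participant_id: str = "sim",
    trial_index: int = 1,
    language_group: str = "monolingual",
) -> Tuple[Trial, GroundTruth]:
    """Generate one trial plus its ground truth, reproducibly from the seed."""
    T = 60.0 / config.tempo_bpm
    metronome = build_metronome(config.tempo_bpm, config.duration_s)
    rng = np.random.default_rng(config.seed)

    taps: List[float] = [0.0]  # first tap on the first tick
    psi_unwrapped: List[float] = []
    warning_time = config.lead_in_beats * T
    lapped = False
    beats_after_lap = 0
    prev_raw = None
    psi = 0.0

    t = 0.0
    while True:
        A = nearest_tick_offset(t, metronome)
        raw = -TWO_PI * A / T
        if prev_raw is None:
            psi = raw
        else:
            step = np.pi - np.mod(np.pi - (raw - prev_raw), TWO_PI)
            psi = psi + step
        prev_raw = raw
        psi_unwrapped.append(psi)

        if not lapped and psi - psi_unwrapped[0] >= TWO_PI:
            lapped = True
        if lapped and config.resync_stop:
            beats_after_lap += 1
            if beats_after_lap > config.lead_out_beats:
                break

        in_lead_in = len(taps) <= config.lead_in_beats
        resynced = lapped and config.resync_stop
        if in_lead_in or resynced or config.detune_ratio == 0:
            delta, alpha = 0.0, config.correction_gain
        else:  # active phasing: pure drift at the detuned tempo
            delta, alpha = config.detune_ratio, 0.0

        eps = rng.normal(0.0, config.motor_noise_sd) if config.motor_noise_sd else 0.0
        t_next = t + T / (1.0 + delta) - alpha * A + eps
        t_next = max(t_next, t + _MIN_TAP_GAP)  # keep tap order strict
        if t_next > config.duration_s:
            break
        taps.append(t_next)
        t = t_next

    psi_arr = np.asarray(psi_unwrapped[: len(taps)])
    laps = count_laps(psi_arr)
    trial = Trial(
        participant_id=participant_id,
        trial_index=trial_index,
        tempo_bpm=config.tempo_bpm,
        language_group=language_group,
        taps=TapSeries(np.asarray(taps)),
        metronome=metronome,
        warning_time=warning_time,
    )
    truth = GroundTruth(
        lap_count=laps,
        label=label_for_laps(laps),
        psi_true_unwrapped=psi_arr,
        warning_time=warning_time,
    )
    return trial, truth


def simulate_cohort(
    n_participants: int = 25,
    trials_per_participant: int = 21,
    archetype_mix: Optional[Dict[str, float]] = None,
    seed: int = 0,
    tempi: Sequence[int] = VALID_TEMPI,
    motor_noise_sd: float = 0.01,
) -> List[Tuple[Trial, GroundTruth]]:
    """Simulate a full cohort mirroring the study design.

    Each participant performs every tempo in ``tempi`` an equal number of
    times (trials_per_participant must be a multiple of len(tempi)), in
    randomized order; the archetype of each trial is drawn from
    ``archetype_mix``.  Motor noise defaults to 10 ms, a typical human
    tap-timing jitter.  Deterministic given the seed.
    """
    mix = dict(DEFAULT_ARCHETYPE_MIX if archetype_mix is None else archetype_mix)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("archetype mix proportions must sum to 1")
    if trials_per_participant % len(tempi):
        raise ValueError(
            f"trials_per_participant={trials_per_participant} is not a "
            f"multiple of the {len(tempi)} tempi"
        )
    repeats = trials_per_participant // len(tempi)
    names = sorted(mix)
    probs = np.asarray([mix[name] for name in names])
    rng = np.random.default_rng(seed)

    cohort: List[Tuple[Trial, GroundTruth]] = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        group = "monolingual" if p % 2 == 0 else "multilingual"
        order = rng.permutation(np.repeat(tempi, repeats))
        for k, tempo in enumerate(order, start=1):
            name = names[rng.choice(len(names), p=probs)]
            config = archetype_config(
                name,
                tempo_bpm=int(tempo),
                seed=int(rng.integers(2**31)),
                motor_noise_sd=motor_noise_sd,
            )
            trial, truth = simulate_trial(
                config, participant_id=pid, trial_index=k, language_group=group
            )
            cohort.append((trial, truth))
    return cohort


def write_ground_truth(
    cohort: Sequence[Tuple[Trial, GroundTruth]], path: Path | str
) -> Path:
    """Write the per-trial ground-truth table next to a cohort."""
    rows = [
        {
            "participant_id": trial.participant_id,
            "trial_index": trial.trial_index,
            "true_lap_count": truth.lap_count,
            "true_label": truth.label,
        }
        for trial, truth in cohort
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def export_cohort(
    cohort: Sequence[Tuple[Trial, GroundTruth]], directory: Path | str
) -> Tuple[Path, Path]:
    """Write trial files, manifest and ground truth; returns their paths."""
    directory = Path(directory)
    manifest = write_cohort([trial for trial, _ in cohort], directory)
    truth = write_ground_truth(cohort, directory / "ground_truth.csv")
    return manifest, truth
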