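import numpy as np
import pytest

from phaserqa import (
    MetronomeTrack,
    TapSeries,
    Trial,
    build_metronome,
)


@pytest.fixture
def metronome_120() -> MetronomeTrack:
    """Metronome at 120 bpm (T = 0.5 s) over 10 s."""
    return build_metronome(120, 10.0)


@pytest.fixture
def simple_trial(metronome_120) -> Trial:
    """Five taps near the first five ticks."""
    taps = np.array([0.0, 0.52, 0.98, 1.51, 2.0])
    return Trial(
        participant_id="P01",
        trial_index=1,
        tempo_bpm=120,
        language_group="monolingual",
        taps=TapSeries(taps),
        metronome=metronome_120,
    )


def make_trial(taps, tempo_bpm=120, duration=10.0, **meta) -> Trial:
    kwargs = dict(
        participant_id="P01",
        trial_index=1,
        tempo_bpm=tempo_bpm,
        language_group="monolingual",
        taps=TapSeries(np.asarray(taps, dtype=float)),
        metronome=build_metronome(tempo_bpm, duration),
    )
    kwargs.update(meta)
    return Trial(**kwargs)
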