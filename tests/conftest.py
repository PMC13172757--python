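import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from taplab.landmarks import DistanceWaveform, LandmarkSeries


def make_series(n_frames: int = 450, fps: float = 30.0, drop=(),
                radius: float = 0.1, freq: float = 2.0,
                confidence: float = 0.9) -> LandmarkSeries:
    """A clean landmark series: thumb fixed, index oscillating about it."""
    k = np.arange(n_frames)
    t = k / fps
    thumb = np.column_stack([np.full(n_frames, 0.5), np.full(n_frames, 0.5)])
    aperture = radius * (1 + np.sin(2 * np.pi * freq * t)) / 2 + 0.05
    index = thumb + np.column_stack([aperture, np.zeros(n_frames)])
    dropped = np.zeros(n_frames, bool)
    dropped[list(drop)] = True
    index[dropped] = np.nan
    return LandmarkSeries(
        frame_index=k, time_s=t, index_xy=index, thumb_xy=thumb,
        confidence=np.full(n_frames, confidence), dropped=dropped, fps=fps,
    )


def sinusoid_waveform(freq: float = 2.0, amplitude: float = 1.0,
                      fs: float = 50.0, duration: float = 15.0,
                      conditioned: bool = True) -> DistanceWaveform:
    t = np.arange(int(round(duration * fs))) / fs
    d = amplitude * np.sin(2 * np.pi * freq * t)
    prov = ("butterworth:test",) if conditioned else ()
    return DistanceWaveform(t=t, d=d, sample_rate_hz=fs, provenance=prov)


@pytest.fixture
def clean_series():
    return make_series()


@pytest.fixture
def sinusoid():
    return sinusoid_waveform()
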