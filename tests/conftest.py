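import numpy as np
import pytest

from snoreforge.audio import AudioClip, frame_signal
from snoreforge.synth import SynthSpec, PlantedTableSpec, make_dataset, make_planted_table

RATE = 16_000


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sine_clip(freq: float, duration: float = 1.0, amplitude: float = 0.8,
              rate: int = RATE, label=None) -> AudioClip:
    t = np.arange(int(duration * rate)) / rate
    return AudioClip(samples=amplitude * np.sin(2 * np.pi * freq * t), rate=rate,
                     label=label, clip_id=f"sine{freq:g}")


def noise_clip(duration: float = 1.0, rate: int = RATE, seed: int = 0) -> AudioClip:
    g = np.random.default_rng(seed)
    x = g.standard_normal(int(duration * rate))
    return AudioClip(samples=0.5 * x / np.max(np.abs(x)), rate=rate, clip_id=f"noise{seed}")


@pytest.fixture
def tone_100hz():
    return sine_clip(100.0)


@pytest.fixture
def tone_frames(tone_100hz):
    return frame_signal(tone_100hz)


@pytest.fixture(scope="session")
def planted():
    """Small planted table: 10 informative + 90 noise columns, 4 classes."""
    table, informative = make_planted_table(PlantedTableSpec(seed=1))
    return table, informative


@pytest.fixture(scope="session")
def tiny_corpus():
    """12 synthetic snore clips (3 per class) at full separability."""
    return make_dataset(SynthSpec(n_per_class=3, seed=3))


def blobs(n_per_class, centers, scale=0.5, seed=0):
    g = np.random.default_rng(seed)
    X = np.vstack([g.normal(c, scale, size=(n, len(c)))
                   for n, c in zip(n_per_class, centers)])
    y = np.concatenate([np.full(n, i) for i, n in enumerate(n_per_class)])
    return X, y
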