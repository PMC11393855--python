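"""Labeled snore-like synthetic audio and planted-structure feature tables.

The audio generator emulates the VOTE rationale — different vibration
sites produce different source fundamentals and resonances — as a purely
statistical stand-in: each class has its own fundamental frequency and
formant band, clips are harmonic stacks with cycle-level jitter/shimmer
perturbation, formant-shaped band noise, an attack-decay amplitude
envelope, and additive white noise at a target SNR. No clinical claim is
made for the templates.

The planted table generator produces a feature matrix with a known set
of informative columns (class-conditional mean shifts) among pure-noise
columns, the test bed for the wrapper selectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, lfilter

from .audio import AudioClip
from .features import FeatureTable

__all__ = ["SynthSpec", "PlantedTableSpec", "make_clip", "make_dataset",
           "make_planted_table"]

VOTE_CLASSES = ("V", "O", "T", "E")


@dataclass
class SynthSpec:
    """Study conditions for the synthetic snore corpus."""

    n_per_class: int = 50
    classes: tuple[str, ...] = VOTE_CLASSES
    fundamentals: tuple[float, ...] = (110.0, 180.0, 260.0, 340.0)
    n_harmonics: int = 8
    formant_centers: tuple[float, ...] = (500.0, 1000.0, 1800.0, 2800.0)
    formant_widths: tuple[float, ...] = (200.0, 300.0, 400.0, 500.0)
    jitter_pct: float = 0.02
    shimmer_pct: float = 0.05
    snr_db: float = 20.0
    separability: float = 1.0
    duration_s: float = 1.0
    rate: int = 16_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.separability <= 1.0:
            raise ValueError("separability must lie in (0, 1]")


def _class_params(spec: SynthSpec, class_id: str) -> tuple[float, float, float]:
    idx = spec.classes.index(class_id)
    s = spec.separability
    f0s = np.asarray(spec.fundamentals)
    fcs = np.asarray(spec.formant_centers)
    # separability < 1 shrinks class templates toward the grand mean
    f0 = f0s.mean() + s * (f0s[idx] - f0s.mean())
    fc = fcs.mean() + s * (fcs[idx] - fcs.mean())
    return float(f0), float(fc), float(spec.formant_widths[idx])


def make_clip(spec: SynthSpec, class_id: str, rng: np.random.Generator,
              clip_id: str = "") -> AudioClip:
    """One snore-like clip for ``class_id``: jittered harmonic stack +
    formant band noise + attack-decay envelope + additive noise."""
    f0, fc, fw = _class_params(spec, class_id)
    n = int(round(spec.duration_s * spec.rate))
    t = np.arange(n) / spec.rate

    # slow (~8 Hz) frequency modulation models cycle-to-cycle jitter
    mod = _smooth_noise(rng, n, spec.rate, cutoff=8.0)
    inst_f = f0 * (1.0 + spec.jitter_pct * mod)
    phase = 2.0 * np.pi * np.cumsum(inst_f) / spec.rate
    source = np.zeros(n)
    for h in range(1, spec.n_harmonics + 1):
        source += np.sin(h * phase + rng.uniform(0, 2 * np.pi)) / h
    source *= 1.0 + spec.shimmer_pct * _smooth_noise(rng, n, spec.rate, cutoff=12.0)

    lo = max(fc - fw, 40.0) / (spec.rate / 2)
    hi = min(fc + fw, spec.rate / 2 - 100.0) / (spec.rate / 2)
    b, a = butter(2, [lo, hi], btype="band")
    formant = lfilter(b, a, rng.standard_normal(n))
    formant *= _rms(source) / max(_rms(formant), 1e-12) * 0.5

    x = source + formant

    # linear 10% attack, then exponential decay
    attack_len = max(1, int(0.1 * n))
    env = np.ones(n)
    env[:attack_len] = np.linspace(0.0, 1.0, attack_len)
    env[attack_len:] = np.exp(-1.2 * (t[attack_len:] - t[attack_len]) / spec.duration_s)
    x *= env

    if np.isfinite(spec.snr_db):
        noise = rng.standard_normal(n)
        noise *= _rms(x) / max(_rms(noise), 1e-12) * 10.0 ** (-spec.snr_db / 20.0)
        x = x + noise

    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak
    return AudioClip(samples=x, rate=spec.rate, label=class_id, clip_id=clip_id)


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x**2)))


def _smooth_noise(rng: np.random.Generator, n: int, rate: int, cutoff: float) -> np.ndarray:
    b, a = butter(2, cutoff / (rate / 2), btype="low")
    x = lfilter(b, a, rng.standard_normal(n))
    s = np.std(x)
    return x / s if s > 0 else x


def make_dataset(spec: SynthSpec) -> list[AudioClip]:
    """Balanced labeled clip list, shuffled with the spec seed."""
    rng = np.random.default_rng(spec.seed)
    clips = []
    for c in spec.classes:
        for i in range(spec.n_per_class):
            clips.append(make_clip(spec, c, rng, clip_id=f"{c}{i:03d}"))
    order = rng.permutation(len(clips))
    return [clips[i] for i in order]


@dataclass
class PlantedTableSpec:
    """Feature table with known informative columns among noise columns."""

    n_samples: int = 200
    n_informative: int = 10
    n_noise: int = 90
    n_classes: int = 4
    class_sep: float = 2.0
    seed: int = 0


def make_planted_table(spec: PlantedTableSpec) -> tuple[FeatureTable, np.ndarray]:
    """(table, informative column indices).

    Each informative column carries a class-conditional mean shift of
    exactly ``class_sep`` standard deviations: a random non-trivial
    bipartition of the classes is shifted by +class_sep relative to the
    rest (then centered). A single column therefore separates only one
    class grouping weakly, and the selectors must keep the whole
    informative set to cover all class contrasts — the behaviour real
    redundant-and-complementary acoustic features show. Noise columns
    are i.i.d. standard normal; informative columns are scattered through
    the table by a seeded permutation.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.n_informative + spec.n_noise
    y = np.repeat(np.arange(spec.n_classes), int(np.ceil(spec.n_samples / spec.n_classes)))
    y = y[: spec.n_samples]
    rng.shuffle(y)
    X = rng.standard_normal((spec.n_samples, d))
    perm = rng.permutation(d)
    informative = np.sort(perm[: spec.n_informative])
    for col in informative:
        size = int(rng.integers(1, spec.n_classes))  # non-trivial bipartition
        group = rng.choice(spec.n_classes, size=size, replace=False)
        means = np.where(np.isin(np.arange(spec.n_classes), group), spec.class_sep, 0.0)
        means -= means.mean()
        X[:, col] += means[y]
    names = [f"f{j:03d}" for j in range(d)]
    labels = np.array([f"c{c}" for c in y])
    return FeatureTable(names=names, X=X, labels=labels), informative
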