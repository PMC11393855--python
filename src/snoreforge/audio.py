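"""Mono audio I/O, normalization, resampling and overlapping framing.

All feature extractors in :mod:`snoreforge.features` consume the
:class:`FrameSet` produced here, so framing conventions (frame length,
hop, analysis window) are decided once, in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

TARGET_RATE = 16_000

__all__ = [
    "AudioClip",
    "FrameSet",
    "read_wav",
    "write_wav",
    "resample",
    "frame_signal",
    "TARGET_RATE",
]


@dataclass
class AudioClip:
    """A mono waveform with amplitudes in [-1, 1].

    Parameters
    ----------
    samples : ndarray
        Amplitude samples; maximum absolute value at most 1.
    rate : int
        Sampling rate in Hz.
    label : str or None
        Optional class identifier (e.g. one of the VOTE snore classes).
    clip_id : str
        Identifier used in feature tables and reports.
    """

    samples: np.ndarray
    rate: int
    label: str | None = None
    clip_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.samples.size == 0:
            raise ValueError("AudioClip requires at least one sample")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class FrameSet:
    """Overlapping windowed frames cut from one clip."""

    frames: np.ndarray  # (num_frames, frame_length)
    frame_length: int
    hop: int
    window_name: str
    rate: int
    raw_frames: np.ndarray = field(repr=False, default=None)  # before windowing

    @property
    def num_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Center time (s) of every frame."""
        starts = np.arange(self.num_frames) * self.hop
        return (starts + self.frame_length / 2.0) / self.rate


def read_wav(path, *, peak_normalize: bool = False, resample_to: int | None = TARGET_RATE,
             clip_id: str | None = None, label: str | None = None) -> AudioClip:
    """Read a PCM WAV file into an :class:`AudioClip`.

    Integer PCM is scaled by the type's full range (32768 for 16-bit), so
    absolute levels stay comparable across clips; multi-channel input is
    averaged down to mono. By default the clip is resampled to 16 kHz, the
    rate the corpus this pipeline targets was preprocessed at.
    """
    rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:  # pragma: no cover - wavfile rejects exotic encodings first
        raise ValueError(f"unsupported WAV sample format: {data.dtype}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    if peak_normalize:
        peak = np.max(np.abs(samples))
        if peak > 0:
            samples = samples / peak
    clip = AudioClip(samples=samples, rate=int(rate), label=label,
                     clip_id=clip_id if clip_id is not None else str(path))
    if resample_to is not None and clip.rate != resample_to:
        clip = resample(clip, resample_to)
    return clip


def write_wav(path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV."""
    x = np.clip(clip.samples, -1.0, 1.0)
    pcm = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, clip.rate, pcm)


def resample(clip: AudioClip, rate: int) -> AudioClip:
    """Polyphase resampling to ``rate`` Hz."""
    if rate == clip.rate:
        return clip
    g = np.gcd(int(clip.rate), int(rate))
    samples = resample_poly(clip.samples, rate // g, clip.rate // g)
    return AudioClip(samples=samples, rate=rate, label=clip.label, clip_id=clip.clip_id)


def frame_signal(clip: AudioClip, frame_ms: float = 25.0, hop_ms: float = 10.0,
                 window_name: str = "hamming") -> FrameSet:
    """Cut a clip into overlapping frames of quasi-stationary signal.

    ``num_frames = floor((len - frame_length)/hop) + 1``; a trailing
    partial frame is dropped. ``window_name='rect'`` leaves frames
    unweighted.
    """
    frame_length = int(round(frame_ms * clip.rate / 1000.0))
    hop = int(round(hop_ms * clip.rate / 1000.0))
    if frame_length < 2:
        raise ValueError("frame must span at least 2 samples")
    if hop <= 0:
        raise ValueError("hop must be positive")
    n = clip.samples.size
    if n < frame_length:
        raise ValueError(f"clip of {n} samples shorter than one frame ({frame_length})")
    raw = np.lib.stride_tricks.sliding_window_view(clip.samples, frame_length)[::hop].copy()
    if window_name in ("rect", "rectangular", "boxcar"):
        win = np.ones(frame_length)
    else:
        win = get_window(window_name, frame_length, fftbins=True)
    return FrameSet(frames=raw * win, frame_length=frame_length, hop=hop,
                    window_name=window_name, rate=clip.rate, raw_frames=raw)
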