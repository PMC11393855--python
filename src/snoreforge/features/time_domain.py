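"""Time-domain descriptors: ZCR family, energy, envelope and periodicity measures.

Per-frame quantities are computed on the un-windowed frames (sign and
amplitude patterns would be distorted by tapering); clip-level features
aggregate them as mean/std.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import argrelmax

from ..audio import AudioClip, FrameSet
from ._lpc import lpc_residual

EPS = 1e-10

__all__ = [
    "zero_crossing_rate",
    "modified_zcr",
    "short_time_energy",
    "time_domain_features",
]


def _sgn(x: np.ndarray) -> np.ndarray:
    # sgn(p) = 1 for p >= 0, else 0 (zero counts as positive)
    return (np.asarray(x) >= 0).astype(np.float64)


def zero_crossing_rate(frame: np.ndarray) -> float:
    """Z = (1/2N) * sum_n |sgn(p(n)) - sgn(p(n-1))| over the N-sample frame.

    Lies in [0, (N-1)/(2N)]; high for unvoiced/noisy content, zero for
    silence or a one-signed frame.
    """
    frame = np.asarray(frame, dtype=np.float64)
    n = frame.size
    if n < 2:
        raise ValueError("ZCR needs a frame of at least 2 samples")
    s = _sgn(frame)
    return float(np.abs(np.diff(s)).sum() / (2.0 * n))


def modified_zcr(frame: np.ndarray) -> float:
    """ZCR after mean removal (detrended), robust to DC offset."""
    frame = np.asarray(frame, dtype=np.float64)
    return zero_crossing_rate(frame - frame.mean())


def short_time_energy(frame: np.ndarray) -> float:
    """Mean energy (1/N) * sum p(n)^2 of one frame."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0:
        raise ValueError("empty frame")
    return float(np.mean(frame**2))


def _frame_wise(frames: np.ndarray, fn) -> np.ndarray:
    return np.array([fn(f) for f in frames])


def time_domain_features(clip: AudioClip, frames: FrameSet) -> tuple[list[str], np.ndarray]:
    """Clip-level time-domain feature vector.

    Includes mean/std of per-frame STE, ZCR and detrended ZCR; the
    energy-weighted temporal centroid (s); clip RMS volume; shimmer
    (mean cycle-to-cycle peak-amplitude change over mean amplitude);
    log attack time (log10 of the 10%->90% envelope rise, s);
    the lag (s) and value of the strongest non-zero-lag autocorrelation
    peak; and LP-ZCR, the ratio of the signal's ZCR to the ZCR of its
    order-12 linear-prediction residual. Silent clips get sentinel 0 for
    LAT and LP-ZCR instead of NaN.
    """
    raw = frames.raw_frames
    ste = np.mean(raw**2, axis=1)
    zcr = _frame_wise(raw, zero_crossing_rate)
    mzcr = _frame_wise(raw, modified_zcr)

    silent = not np.any(np.abs(clip.samples) > 0)

    # temporal centroid: energy-weighted mean frame time
    if ste.sum() > 0:
        centroid = float(np.dot(frames.times, ste) / ste.sum())
    else:
        centroid = float(clip.duration / 2.0)

    volume = float(np.sqrt(np.mean(clip.samples**2)))

    peaks = np.max(np.abs(raw), axis=1)
    mean_amp = peaks.mean()
    if peaks.size >= 2 and mean_amp > 0:
        shimmer = float(np.mean(np.abs(np.diff(peaks))) / mean_amp)
    else:
        shimmer = 0.0

    # log attack time on the per-frame RMS envelope
    env = np.sqrt(ste)
    if silent or env.max() <= 0:
        lat = 0.0
    else:
        t10 = int(np.argmax(env >= 0.1 * env.max()))
        t90 = int(np.argmax(env >= 0.9 * env.max()))
        dt = max(t90 - t10, 1) * frames.hop / frames.rate
        lat = float(np.log10(dt))

    ac_lag, ac_val = _autocorr_peak(clip.samples, clip.rate)

    if silent:
        lp_zcr = 0.0
    else:
        z_sig = zero_crossing_rate(clip.samples)
        resid = lpc_residual(clip.samples, order=12)
        z_res = zero_crossing_rate(resid)
        lp_zcr = float(z_sig / z_res) if z_res > 0 else 0.0

    names = [
        "time.ste.mean", "time.ste.std",
        "time.zcr.mean", "time.zcr.std",
        "time.mzcr.mean", "time.mzcr.std",
        "time.temporal_centroid", "time.volume_rms", "time.shimmer",
        "time.lat", "time.autocorr_lag", "time.autocorr_value", "time.lp_zcr",
    ]
    values = np.array([
        ste.mean(), ste.std(), zcr.mean(), zcr.std(), mzcr.mean(), mzcr.std(),
        centroid, volume, shimmer, lat, ac_lag, ac_val, lp_zcr,
    ])
    return names, values


def _autocorr_peak(x: np.ndarray, rate: int) -> tuple[float, float]:
    """Lag (s) and normalized value of the highest non-zero-lag autocorrelation peak."""
    x = x - x.mean()
    n = x.size
    if not np.any(x):
        return 0.0, 0.0
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[: n // 2]
    if ac[0] <= 0:
        return 0.0, 0.0
    ac = ac / ac[0]
    peaks = argrelmax(ac)[0]
    peaks = peaks[peaks > 0]
    if peaks.size == 0:
        return 0.0, 0.0
    best = peaks[np.argmax(ac[peaks])]
    return float(best / rate), float(ac[best])
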