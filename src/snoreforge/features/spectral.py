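"""Frequency-domain descriptors.

Covers the spectral-shape set (centroid, spread, skewness, kurtosis,
flatness, crest, roll-off, slope, decrease, bandwidth, entropy, flux,
octave-band spectral contrast), long-term average spectrum statistics of
the frame-RMS series, tonality measures (F0, jitter, harmonic-to-noise
ratio, peak frequency) and autoregressive features (LPC + line spectral
frequencies).

Spectra are magnitudes of the FFT of the Hamming-windowed frames; power
is magnitude squared. Logs and ratios are floored at 1e-10.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..audio import AudioClip, FrameSet
from ._lpc import lpc_coefficients, line_spectral_frequencies

EPS = 1e-10

OCTAVE_EDGES = [125.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0]

__all__ = [
    "spectral_shape_features",
    "ltas_features",
    "tonality_features",
    "autoregressive_features",
]


def _magnitude_spectra(frames: FrameSet) -> tuple[np.ndarray, np.ndarray]:
    mag = np.abs(np.fft.rfft(frames.frames, axis=1))
    freqs = np.fft.rfftfreq(frames.frame_length, d=1.0 / frames.rate)
    return mag, freqs


def spectral_shape_features(frames: FrameSet) -> tuple[list[str], np.ndarray]:
    """Mean/std over frames of the spectral-shape descriptors."""
    mag, freqs = _magnitude_spectra(frames)
    power = mag**2
    nf, nb = mag.shape

    psum = power.sum(axis=1)
    p_norm = power / np.maximum(psum, EPS)[:, None]

    centroid = p_norm @ freqs
    spread = np.sqrt(np.maximum((p_norm * (freqs[None, :] - centroid[:, None]) ** 2).sum(axis=1), 0.0))
    dev = freqs[None, :] - centroid[:, None]
    sp = np.maximum(spread, EPS)
    skewness = (p_norm * dev**3).sum(axis=1) / sp**3
    kurtosis = (p_norm * dev**4).sum(axis=1) / sp**4
    # bandwidth: energy-weighted mean absolute deviation from the centroid
    bandwidth = (p_norm * np.abs(dev)).sum(axis=1)

    logp = np.log(np.maximum(power, EPS))
    flatness = np.exp(logp.mean(axis=1)) / np.maximum(power.mean(axis=1), EPS)
    crest = power.max(axis=1) / np.maximum(power.mean(axis=1), EPS)

    cum = np.cumsum(power, axis=1)
    thresh = 0.85 * np.maximum(cum[:, -1], EPS)
    rolloff = freqs[np.argmax(cum >= thresh[:, None], axis=1)]
    # spectral center: median frequency (50% cumulative energy)
    center = freqs[np.argmax(cum >= 0.5 * np.maximum(cum[:, -1], EPS)[:, None], axis=1)]

    fc = freqs - freqs.mean()
    slope = (mag * fc[None, :]).sum(axis=1) / np.dot(fc, fc)

    k = np.arange(1, nb)
    decrease = ((mag[:, 1:] - mag[:, :1]) / k[None, :]).sum(axis=1) / np.maximum(mag[:, 1:].sum(axis=1), EPS)

    pe = np.maximum(p_norm, EPS)
    entropy = -(pe * np.log(pe)).sum(axis=1) / np.log(nb)

    flux = np.zeros(nf)
    if nf >= 2:
        flux[1:] = np.sqrt(((mag[1:] - mag[:-1]) ** 2).sum(axis=1))

    contrasts = _octave_band_contrast(mag, freqs)

    names: list[str] = []
    cols: list[np.ndarray] = []
    scalar = {
        "centroid": centroid, "spread": spread, "skewness": skewness,
        "kurtosis": kurtosis, "flatness": flatness, "crest": crest,
        "rolloff": rolloff, "center": center, "slope": slope,
        "decrease": decrease, "bandwidth": bandwidth, "entropy": entropy,
    }
    for key, series in scalar.items():
        names += [f"freq.{key}.mean", f"freq.{key}.std"]
        cols += [series.mean(), series.std()]
    # flux statistics exclude the first frame, which has no predecessor
    fl = flux[1:] if nf >= 2 else np.zeros(1)
    names += ["freq.flux.mean", "freq.flux.std"]
    cols += [fl.mean(), fl.std()]
    for b in range(contrasts.shape[1]):
        names += [f"freq.obsc{b + 1}.mean", f"freq.obsc{b + 1}.std"]
        cols += [contrasts[:, b].mean(), contrasts[:, b].std()]
    return names, np.array(cols, dtype=np.float64)


def _octave_band_contrast(mag: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Per-band log(peak) - log(valley) with 0.2-quantile neighborhoods."""
    out = np.zeros((mag.shape[0], len(OCTAVE_EDGES) - 1))
    for b in range(len(OCTAVE_EDGES) - 1):
        lo, hi = OCTAVE_EDGES[b], OCTAVE_EDGES[b + 1]
        idx = np.flatnonzero((freqs >= lo) & (freqs < hi))
        if idx.size == 0:
            continue
        band = np.sort(mag[:, idx], axis=1)
        m = max(1, int(round(0.2 * idx.size)))
        valley = np.maximum(band[:, :m].mean(axis=1), EPS)
        peak = np.maximum(band[:, -m:].mean(axis=1), EPS)
        out[:, b] = np.log(peak) - np.log(valley)
    return out


def ltas_features(frames: FrameSet) -> tuple[list[str], np.ndarray]:
    """Statistics of the per-frame RMS series: range, skewness, kurtosis,
    mean, normalized std and mean pairwise variability.

    A constant series gets skewness/kurtosis 0 by convention.
    """
    if frames.num_frames < 4:
        raise ValueError("LTAS statistics need at least 4 frames")
    rms = np.sqrt(np.mean(frames.raw_frames**2, axis=1))
    rng = float(rms.max() - rms.min())
    if np.ptp(rms) < EPS * max(rms.max(), 1.0):
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(rms))
        kurt = float(stats.kurtosis(rms))
    mean = float(rms.mean())
    cv = float(rms.std() / mean) if mean > 0 else 0.0
    ppv = float(np.mean(np.abs(np.diff(rms))))
    names = ["freq.ltas_range", "freq.ltas_skew", "freq.ltas_kurt",
             "freq.ltas_mean", "freq.ltas_cv", "freq.ltas_ppv"]
    return names, np.array([rng, skew, kurt, mean, cv, ppv])


def _frame_f0(frame: np.ndarray, rate: int, fmin: float, fmax: float,
              threshold: float) -> tuple[float, float]:
    """(F0 Hz, normalized autocorrelation at the F0 lag); (0, 0) if unvoiced."""
    x = frame - frame.mean()
    n = x.size
    e0 = np.dot(x, x)
    if e0 <= 0:
        return 0.0, 0.0
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[:n]
    ac = ac / ac[0]
    lo = max(2, int(np.floor(rate / fmax)))
    hi = min(n - 1, int(np.ceil(rate / fmin)))
    if hi <= lo:
        return 0.0, 0.0
    seg = ac[lo : hi + 1]
    best = int(np.argmax(seg))
    r = float(seg[best])
    if r < threshold:
        return 0.0, 0.0
    return rate / (lo + best), r


def tonality_features(clip: AudioClip, frames: FrameSet, *, fmin: float = 50.0,
                      fmax: float = 500.0, voicing_threshold: float = 0.3
                      ) -> tuple[list[str], np.ndarray]:
    """F0 statistics, jitter, harmonic-to-noise ratio and peak frequency.

    F0 is estimated per frame from the normalized autocorrelation peak
    restricted to the 50-500 Hz snore range; frames whose peak falls below
    the voicing threshold are treated as unvoiced. Jitter is the mean
    absolute cycle-period change over the mean period; HNR in dB is
    10*log10(r/(1-r)) at the F0 lag. Unvoiced clips get sentinel 0 for
    F0/jitter/HNR.
    """
    est = np.array([_frame_f0(f, frames.rate, fmin, fmax, voicing_threshold)
                    for f in frames.raw_frames])
    f0s, rs = est[:, 0], est[:, 1]
    voiced = f0s > 0
    if voiced.any():
        f0_mean = float(f0s[voiced].mean())
        f0_std = float(f0s[voiced].std())
        periods = 1.0 / f0s[voiced]
        if periods.size >= 2:
            jitter = float(np.mean(np.abs(np.diff(periods))) / periods.mean())
        else:
            jitter = 0.0
        r = np.clip(rs[voiced], EPS, 1.0 - 1e-9)
        hnr = float(np.mean(10.0 * np.log10(r / (1.0 - r))))
    else:
        f0_mean = f0_std = jitter = hnr = 0.0

    x = clip.samples - clip.samples.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / clip.rate)
    peak_freq = float(freqs[int(np.argmax(spec))]) if np.any(spec > 0) else 0.0

    names = ["freq.f0.mean", "freq.f0.std", "freq.jitter", "freq.hnr", "freq.peak_freq"]
    return names, np.array([f0_mean, f0_std, jitter, hnr, peak_freq])


def autoregressive_features(frames: FrameSet, order: int = 12) -> tuple[list[str], np.ndarray]:
    """Per-clip mean of frame LPC coefficients and line spectral frequencies."""
    if order >= frames.frame_length:
        raise ValueError("LPC order must be below the frame length")
    lpcs = np.array([lpc_coefficients(f, order) for f in frames.raw_frames])
    lsfs = np.array([line_spectral_frequencies(a) for a in lpcs])
    names = [f"freq.lpc{k + 1:02d}" for k in range(order)]
    names += [f"freq.lsf{k + 1:02d}" for k in range(order)]
    return names, np.concatenate([lpcs.mean(axis=0), lsfs.mean(axis=0)])
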