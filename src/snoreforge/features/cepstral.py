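"""Cepstral features: MFCC, LPCC and gammatone cepstral coefficients.

MFCC: power spectrum of the windowed frames -> 26 triangular mel filters
-> log (floored at 1e-10) -> orthonormal DCT-II -> 13 coefficients.
GTCC follows the same path with a 26-channel gammatone filterbank.
LPCC applies the standard LPC-to-cepstrum recursion to order-12 LPC.
Aggregation is clip mean/std, plus the means of the delta-MFCCs.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dct

from ..audio import FrameSet
from ._lpc import lpc_coefficients

EPS = 1e-10
N_COEF = 13
N_FILTERS = 26

__all__ = ["mel_filterbank", "gammatone_filterbank", "mfcc", "lpcc", "cepstral_features"]


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, n_fft_bins: int, rate: int,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular filters on the mel scale, (n_filters, n_fft_bins)."""
    if fmax is None:
        fmax = rate / 2.0
    mels = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_filters + 2)
    edges = _mel_to_hz(mels)
    freqs = np.linspace(0.0, rate / 2.0, n_fft_bins)
    fb = np.zeros((n_filters, n_fft_bins))
    for i in range(n_filters):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        rising = (freqs - lo) / max(mid - lo, EPS)
        falling = (hi - freqs) / max(hi - mid, EPS)
        fb[i] = np.maximum(0.0, np.minimum(rising, falling))
    return fb


def _hz_to_erb(f):
    return 21.4 * np.log10(1.0 + 0.00437 * np.asarray(f))


def _erb_to_hz(e):
    return (10.0 ** (np.asarray(e) / 21.4) - 1.0) / 0.00437


def gammatone_filterbank(n_filters: int, n_fft_bins: int, rate: int,
                         fmin: float = 50.0, fmax: float | None = None) -> np.ndarray:
    """Magnitude responses of 4th-order gammatone filters, ERB-spaced centers.

    |H(f)| proportional to [1 + ((f - fc)/b)^2]^(-2) with bandwidth
    b = 1.019 * ERB(fc); rows are peak-normalized.
    """
    if fmax is None:
        fmax = rate / 2.0
    centers = _erb_to_hz(np.linspace(_hz_to_erb(fmin), _hz_to_erb(fmax), n_filters))
    freqs = np.linspace(0.0, rate / 2.0, n_fft_bins)
    erb = 24.7 * (1.0 + 4.37 * centers / 1000.0)
    b = 1.019 * erb
    resp = (1.0 + ((freqs[None, :] - centers[:, None]) / b[:, None]) ** 2) ** -2
    return resp / resp.max(axis=1, keepdims=True)


def _filterbank_cepstra(frames: FrameSet, fb: np.ndarray) -> np.ndarray:
    power = np.abs(np.fft.rfft(frames.frames, axis=1)) ** 2
    energies = power @ fb.T
    logs = np.log(np.maximum(energies, EPS))
    return dct(logs, type=2, norm="ortho", axis=1)[:, :N_COEF]


def mfcc(frames: FrameSet, n_filters: int = N_FILTERS) -> np.ndarray:
    """(num_frames, 13) mel-frequency cepstral coefficients (c0..c12)."""
    n_bins = frames.frame_length // 2 + 1
    fb = mel_filterbank(n_filters, n_bins, frames.rate)
    return _filterbank_cepstra(frames, fb)


def gtcc(frames: FrameSet, n_filters: int = N_FILTERS) -> np.ndarray:
    """(num_frames, 13) gammatone cepstral coefficients."""
    n_bins = frames.frame_length // 2 + 1
    fb = gammatone_filterbank(n_filters, n_bins, frames.rate)
    return _filterbank_cepstra(frames, fb)


def lpcc(a: np.ndarray, n_coef: int = N_COEF) -> np.ndarray:
    """Cepstral coefficients c1..c_n from error-filter coefficients a1..ap.

    Recursion: c1 = -a1; c_n = -a_n - sum_{k=1}^{n-1} (k/n) c_k a_{n-k},
    with a_n = 0 for n > p.
    """
    p = a.size
    c = np.zeros(n_coef)
    for n in range(1, n_coef + 1):
        an = a[n - 1] if n <= p else 0.0
        acc = sum((k / n) * c[k - 1] * a[n - k - 1] for k in range(1, n) if n - k <= p)
        c[n - 1] = -an - acc
    return c


def cepstral_features(frames: FrameSet, lpc_order: int = 12) -> tuple[list[str], np.ndarray]:
    """Clip mean/std of 13 MFCCs, 13 LPCCs and 13 GTCCs plus delta-MFCC means."""
    m = mfcc(frames)
    g = gtcc(frames)
    lp = np.array([lpcc(lpc_coefficients(f, lpc_order)) for f in frames.raw_frames])
    delta = np.gradient(m, axis=0) if m.shape[0] >= 2 else np.zeros_like(m)

    names: list[str] = []
    values: list[np.ndarray] = []
    for tag, mat in (("mfcc", m), ("lpcc", lp), ("gtcc", g)):
        for i in range(mat.shape[1]):
            names += [f"cep.{tag}{i:02d}.mean", f"cep.{tag}{i:02d}.std"]
            values += [mat[:, i].mean(), mat[:, i].std()]
    for i in range(delta.shape[1]):
        names.append(f"cep.dmfcc{i:02d}.mean")
        values.append(delta[:, i].mean())
    return names, np.array(values)
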