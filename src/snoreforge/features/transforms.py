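"""Wavelet, sparse-coding and eigen-domain features.

The wavelet set summarizes the energy distribution of a multilevel DWT;
the sparse set summarizes an orthogonal-matching-pursuit decomposition on
an overcomplete DCT dictionary; the eigen set summarizes the singular
value spectrum of the frame matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt

from ..audio import AudioClip, FrameSet

EPS = 1e-10

__all__ = ["dwt_features", "omp_decompose", "dct_dictionary", "sparse_features",
           "eigen_features"]


def dwt_features(clip: AudioClip, wavelet: str = "db4", levels: int = 5
                 ) -> tuple[list[str], np.ndarray]:
    """Sub-band descriptors of a ``levels``-deep DWT (A_L, D_L .. D_1).

    Per band: relative energy (the six values sum to 1), log10 total band
    energy, mean absolute coefficient, coefficient std, and Shannon
    entropy of the normalized squared coefficients (normalized to [0, 1]).
    Clips too short for the requested depth are analyzed at the deepest
    admissible level with a warning.
    """
    x = clip.samples
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(wavelet).dec_len)
    if levels > max_level:
        warnings.warn(f"clip supports only {max_level} DWT levels; reducing from {levels}")
        levels = max(1, max_level)
    coefs = pywt.wavedec(x, wavelet, level=levels, mode="periodization")
    band_names = [f"a{levels}"] + [f"d{lev}" for lev in range(levels, 0, -1)]
    energies = np.array([np.sum(c**2) for c in coefs])
    total = max(energies.sum(), EPS)
    names: list[str] = []
    values: list[float] = []
    for band, c, e in zip(band_names, coefs, energies):
        p = c**2 / max(e, EPS)
        p = np.maximum(p, EPS)
        ent = float(-(p * np.log(p)).sum() / np.log(max(c.size, 2)))
        names += [f"dwt.{band}.relenergy", f"dwt.{band}.logenergy",
                  f"dwt.{band}.meanabs", f"dwt.{band}.std", f"dwt.{band}.entropy"]
        values += [e / total, np.log10(e + EPS), np.mean(np.abs(c)), np.std(c), ent]
    return names, np.array(values)


def dct_dictionary(signal_len: int, dict_size: int) -> np.ndarray:
    """Overcomplete DCT dictionary: ``signal_len`` x ``dict_size``, unit-norm atoms."""
    n = np.arange(signal_len)[:, None]
    k = np.arange(dict_size)[None, :]
    D = np.cos(np.pi * (n + 0.5) * k / dict_size)
    return D / np.linalg.norm(D, axis=0, keepdims=True)


def omp_decompose(x: np.ndarray, dictionary: np.ndarray, k: int
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthogonal matching pursuit: greedy max-correlation atom selection
    with a least-squares re-fit on the active set at every step.

    Returns (selected atom indices, their final coefficients, residual
    energy fraction after each of the k steps).
    """
    if k > dictionary.shape[1]:
        raise ValueError("k cannot exceed the dictionary size")
    residual = x.astype(np.float64).copy()
    e0 = max(np.dot(x, x), EPS)
    support: list[int] = []
    fractions = np.zeros(k)
    coef = np.zeros(0)
    for step in range(k):
        corr = np.abs(dictionary.T @ residual)
        corr[support] = -1.0
        support.append(int(np.argmax(corr)))
        sub = dictionary[:, support]
        coef, *_ = np.linalg.lstsq(sub, x, rcond=None)
        residual = x - sub @ coef
        fractions[step] = np.dot(residual, residual) / e0
    return np.asarray(support), coef, fractions


def sparse_features(clip: AudioClip, dict_size: int | None = None, k: int = 20,
                    window: int = 256) -> tuple[list[str], np.ndarray]:
    """OMP sparse-decomposition summary of the clip's central window.

    The window is normalized by its mean magnitude before decomposition on
    a 2x-overcomplete DCT dictionary. Features: residual energy fraction
    at the four quartile steps of the pursuit, mean/std of the absolute
    selected coefficients, and the normalized index spread of the chosen
    atoms.
    """
    n = min(window, clip.samples.size)
    start = (clip.samples.size - n) // 2
    x = clip.samples[start : start + n].astype(np.float64)
    scale = np.mean(np.abs(x))
    if scale > 0:
        x = x / scale
    if dict_size is None:
        dict_size = 2 * n
    D = dct_dictionary(n, dict_size)
    support, coef, fractions = omp_decompose(x, D, k)
    q = [fractions[max(0, int(np.ceil(qq * k)) - 1)] for qq in (0.25, 0.5, 0.75, 1.0)]
    ac = np.abs(coef)
    spread = float(np.std(support) / dict_size)
    names = ["sparse.resid.q25", "sparse.resid.q50", "sparse.resid.q75",
             "sparse.resid.final", "sparse.coef.meanabs", "sparse.coef.stdabs",
             "sparse.atom_spread"]
    return names, np.array(q + [ac.mean(), ac.std(), spread])


def eigen_features(frames: FrameSet, top_k: int = 10) -> tuple[list[str], np.ndarray]:
    """Singular-value spectrum of the grand-mean-centered frame matrix.

    Features: the top-k singular values normalized so the full spectrum
    sums to 1, the cumulative energy of the top 3, and the Shannon
    entropy of the normalized spectrum. Identical repeated frames give a
    rank-1 matrix: first normalized value 1, rest 0.
    """
    if frames.num_frames < top_k:
        raise ValueError(f"need at least top_k={top_k} frames, got {frames.num_frames}")
    M = frames.raw_frames - frames.raw_frames.mean()
    sv = np.linalg.svd(M, compute_uv=False)
    total = sv.sum()
    p = sv / total if total > 0 else np.zeros_like(sv)
    topk = p[:top_k]
    cum3 = float(p[:3].sum())
    pe = p[p > EPS]
    ent = float(-(pe * np.log(pe)).sum()) if pe.size else 0.0
    names = [f"eigen.sv{i + 1:02d}" for i in range(top_k)]
    names += ["eigen.cum3", "eigen.entropy"]
    return names, np.concatenate([topk, [cum3, ent]])
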