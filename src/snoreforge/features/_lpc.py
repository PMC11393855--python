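"""Linear-prediction helpers shared by the time, frequency and cepstral domains."""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_toeplitz

__all__ = ["lpc_coefficients", "lpc_residual", "line_spectral_frequencies"]


def lpc_coefficients(x: np.ndarray, order: int) -> np.ndarray:
    """Prediction-error filter coefficients ``a1..a_order``.

    Solves the Yule-Walker equations on the biased autocorrelation of ``x``.
    The convention is the error-filter polynomial A(z) = 1 + a1 z^-1 + ...,
    so for the AR process x(n) = phi1 x(n-1) + ... + e(n), a_k ≈ -phi_k.
    Degenerate input (zero autocorrelation) yields all-zero coefficients.
    """
    x = np.asarray(x, dtype=np.float64)
    if order >= x.size:
        raise ValueError(f"LPC order {order} must be below signal length {x.size}")
    n = x.size
    r = np.array([np.dot(x[: n - k], x[k:]) for k in range(order + 1)]) / n
    if r[0] <= 0:
        return np.zeros(order)
    # small diagonal load keeps near-singular (e.g. pure tone) systems stable
    r0 = r.copy()
    r0[0] *= 1.0 + 1e-9
    try:
        phi = solve_toeplitz(r0[:order], r[1 : order + 1])
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.zeros(order)
    if not np.all(np.isfinite(phi)):
        return np.zeros(order)
    return -phi


def lpc_residual(x: np.ndarray, order: int = 12) -> np.ndarray:
    """Prediction error e(n) = x(n) + sum_k a_k x(n-k)."""
    a = lpc_coefficients(x, order)
    return np.convolve(x, np.concatenate(([1.0], a)))[: x.size]


def line_spectral_frequencies(a: np.ndarray) -> np.ndarray:
    """Line spectral frequencies of the error filter ``[1, a1..ap]`` given as ``a1..ap``.

    Roots of the palindromic/anti-palindromic split polynomials
    P(z) = A(z) + z^-(p+1) A(1/z) and Q(z) = A(z) - z^-(p+1) A(1/z),
    returned as angles in (0, pi), ascending. For a stable (minimum-phase)
    A(z) the P and Q frequencies interlace strictly.
    """
    a = np.asarray(a, dtype=np.float64)
    poly = np.concatenate(([1.0], a))
    p = a.size
    flipped = np.concatenate(([0.0], poly[::-1]))  # z^-(p+1) A(1/z), descending powers
    P = np.concatenate((poly, [0.0])) + flipped
    Q = np.concatenate((poly, [0.0])) - flipped
    freqs = []
    for c in (P, Q):
        roots = np.roots(c)
        ang = np.angle(roots)
        keep = (ang > 1e-9) & (ang < np.pi - 1e-9)
        freqs.extend(ang[keep])
    out = np.sort(np.asarray(freqs))
    return out[:p] if out.size >= p else np.pad(out, (0, p - out.size))
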