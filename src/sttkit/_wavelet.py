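"""Minimal orthogonal discrete wavelet transform (coif4) used by the denoiser.

Implements a multilevel analysis/synthesis filter bank with circular
convolution on a symmetrically pre-extended signal, which gives exact
perfect reconstruction while avoiding edge artefacts inside the signal
proper. Only what the denoising stage needs is provided.
"""

from __future__ import annotations

import numpy as np

# Coiflet-4 low-pass decomposition filter (24 taps, orthonormal).
COIF4_DEC_LO = np.array([
    -1.7849909144933469e-06,
    -3.259647940030751e-06,
    3.1229861599195265e-05,
    6.233885431278719e-05,
    -0.0002599743371222568,
    -0.0005890202246332165,
    0.0012665610789256603,
    0.0037514346971460866,
    -0.0056582838001308835,
    -0.015211728187697211,
    0.02508225333794961,
    0.03933442260558915,
    -0.09622042453595264,
    -0.06662747236681717,
    0.43438603311435653,
    0.7822389344242826,
    0.41530842700068227,
    -0.05607731960356926,
    -0.08126671024919373,
    0.02668230466960483,
    0.01606894713157503,
    -0.007346167936268051,
    -0.001629492425226786,
    0.000892313902537003,
])
COIF4_DEC_LO.setflags(write=False)

# Quadrature mirror: g[k] = (-1)^k h[L-1-k]
COIF4_DEC_HI = (COIF4_DEC_LO[::-1] * (-1.0) ** np.arange(COIF4_DEC_LO.size)).copy()
COIF4_DEC_HI.setflags(write=False)


def _circ_corr_down(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """y[k] = sum_n x[n] filt[n - 2k] with circular indexing (analysis)."""
    n = x.size
    f = np.zeros(n)
    f[: filt.size] = filt
    y = np.fft.irfft(np.fft.rfft(x) * np.conj(np.fft.rfft(f)), n)
    return y[::2]


def _circ_conv_up(c: np.ndarray, filt: np.ndarray, n: int) -> np.ndarray:
    """x[n] = sum_k c[k] filt[n - 2k] with circular indexing (synthesis)."""
    up = np.zeros(n)
    up[::2] = c
    f = np.zeros(n)
    f[: filt.size] = filt
    return np.fft.irfft(np.fft.rfft(up) * np.fft.rfft(f), n)


def wavedec(x: np.ndarray, levels: int) -> list[np.ndarray]:
    """Multilevel coif4 decomposition: [a_L, d_L, ..., d_1].

    Requires len(x) divisible by 2**levels.
    """
    if x.size % (1 << levels):
        raise ValueError(f"signal length {x.size} not divisible by 2^{levels}")
    coeffs: list[np.ndarray] = []
    a = np.asarray(x, dtype=float)
    for _ in range(levels):
        d = _circ_corr_down(a, COIF4_DEC_HI)
        a = _circ_corr_down(a, COIF4_DEC_LO)
        coeffs.append(d)
    coeffs.append(a)
    return coeffs[::-1]


def waverec(coeffs: list[np.ndarray]) -> np.ndarray:
    """Inverse of :func:`wavedec`."""
    a = coeffs[0]
    for d in coeffs[1:]:
        n = 2 * a.size
        a = _circ_conv_up(a, COIF4_DEC_LO, n) + _circ_conv_up(d, COIF4_DEC_HI, n)
    return a


def symmetric_pad(x: np.ndarray, multiple: int, margin: int = 64) -> tuple[np.ndarray, int]:
    """Symmetrically extend x so its length is a multiple of ``multiple``.

    Returns (padded, left_pad). At least ``margin`` samples are added on the
    left so circular wrap-around happens in the extension, not the signal.
    """
    n = x.size
    total = n + 2 * margin
    total += (-total) % multiple
    left = margin
    right = total - n - left
    return np.pad(x, (left, right), mode="symmetric"), left
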