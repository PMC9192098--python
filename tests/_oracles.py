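"""Independent brute-force reference implementations used by the tests.

These deliberately mirror the printed definitions with plain loops /
direct distance computations and share no code with the package's
optimized paths.
"""

import numpy as np


def sampen_oracle(series: np.ndarray, m: int = 2, r: float = 0.1) -> float:
    """Template-counting sample entropy, O(N^2), strict d < r, no self-match.

    phi(m): j over the first N-m templates, match pool all N-m+1 templates.
    phi(m+1): j and z over the N-m templates. Per-j normalizations cancel.
    """
    x = np.asarray(series, dtype=float)
    x = (x - x.mean()) / x.std()
    n = x.size
    tm = np.lib.stride_tricks.sliding_window_view(x, m)
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    b = a = 0
    for j in range(n - m):
        d = np.abs(tm - tm[j]).max(axis=1)
        d[j] = np.inf
        b += int((d < r).sum())
        d1 = np.abs(tm1 - tm1[j]).max(axis=1)
        d1[j] = np.inf
        a += int((d1 < r).sum())
    return float(-np.log(a / b))


def shi_oracle(traj: np.ndarray, step: int = 10, theiler: int = 1) -> float:
    """Nearest-neighbour log-divergence, plain per-point loop."""
    x = np.asarray(traj, dtype=float)
    n = x.shape[0]
    terms = []
    for i in range(n - step):
        d2 = ((x - x[i]) ** 2).sum(axis=1)
        d2[max(0, i - theiler):min(n, i + theiler + 1)] = np.inf
        j = int(np.argmin(d2))
        if not np.isfinite(d2[j]) or j + step >= n:
            continue
        d_start = float(np.sqrt(d2[j]))
        d_end = float(np.sqrt(((x[i + step] - x[j + step]) ** 2).sum()))
        if d_start == 0.0 or d_end == 0.0:
            continue
        terms.append(np.log(d_end / d_start))
    return float(np.mean(terms))


def thi_exponent_oracle(mag: np.ndarray, decay_scale: float = 0.001) -> int:
    """Exhaustive integer scan of the decay exponent, one lambda at a time."""
    mag = np.asarray(mag, dtype=float)
    k = np.arange(mag.size)
    best_lam, best = 1, np.inf
    for lam in range(1, mag.size + 1):
        cost = float(np.abs(mag - mag[0] * np.exp(-decay_scale * lam * k)).sum())
        if cost < best:
            best, best_lam = cost, lam
    return best_lam


def smooth_random_series(rng: np.random.Generator, n: int) -> np.ndarray:
    """AR(1)-filtered noise: rough enough to be generic, smooth enough to
    have template matches at r = 0.1."""
    from scipy.signal import lfilter

    return lfilter([1.0], [1.0, -0.9], rng.normal(size=n))
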