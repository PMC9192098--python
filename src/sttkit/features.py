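"""The 17 candidate features of one record.

* per-lead sample entropy of the spliced, standardized ST-T series
  (12 ECG + 3 VCG leads; m=2, r=0.1 by default, strict ``d < r`` matching
  with Chebyshev distance, self-matches excluded);
* SHI — a Lyapunov-style spatial heterogeneity index of the 3-D VCG ST-T
  trajectory: the mean log-ratio of each point's nearest-neighbour
  distance after a fixed step lag to its initial distance;
* THI — the RMS of per-lead integer exponents of an exponential-decay
  model fitted (L1, exhaustive integer grid) to the magnitude spectra of
  the three VCG ST-T series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import (
    DegenerateSeriesError,
    ShiUndefinedError,
    ThiUndefinedError,
    UndefinedEntropyError,
)
from .io import FEATURE_COLUMNS, LEAD_ORDER, MultiLeadRecord, VCGRecord
from .segment import STTSegmentSet, splice_stt


@dataclass(frozen=True)
class SampEnParams:
    m: int = 2
    r: float = 0.1  # tolerance; series is standardized first, so this is absolute

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not self.r > 0:
            raise ValueError("r must be positive")


@dataclass(frozen=True)
class ShiParams:
    step: int = 10
    neighbor_exclusion: int = 1  # Theiler window, samples

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.neighbor_exclusion < 0:
            raise ValueError("neighbor_exclusion must be >= 0")


@dataclass(frozen=True)
class ThiParams:
    decay_scale: float = 0.001


@dataclass
class FeatureVector:
    """17 features keyed by lead/index name; NaN marks a flagged feature."""

    values: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)

    def as_row(self) -> list[float]:
        return [self.values[c] for c in FEATURE_COLUMNS]

    @property
    def complete(self) -> bool:
        return not self.flags


# ---------------------------------------------------------------------------
# Sample entropy
# ---------------------------------------------------------------------------

def _embed(x: np.ndarray, m: int) -> np.ndarray:
    """All N-m+1 overlapping m-point templates as rows."""
    n = x.size
    return np.lib.stride_tricks.sliding_window_view(x, m).reshape(n - m + 1, m)


def _strict_pair_count(a: np.ndarray, b: np.ndarray, r: float) -> int:
    """Ordered pairs (i, j) with Chebyshev distance strictly below r.

    KD-tree count_neighbors uses closed balls; subtracting the count at the
    largest float below r removes pairs at exactly distance r.
    """
    ta, tb = cKDTree(a), cKDTree(b)
    below = np.nextafter(r, -np.inf)
    closed, open_ = ta.count_neighbors(tb, np.array([r, below]), p=np.inf)
    ties = closed - open_
    return int(closed - ties)


def sample_entropy(series: np.ndarray, p: SampEnParams = SampEnParams()) -> float:
    """SampEn(N, m, r) = -ln(phi(m+1) / phi(m)) of a standardized series.

    Matches are counted with strict inequality and without self-matches;
    the template pools follow the printed index ranges: at length m the
    match pool is all N-m+1 templates, at m+1 all N-m templates, and both
    numerator and denominator average over j = 1..N-m (the per-j
    normalization constants cancel in the ratio).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n <= p.m + 1:
        raise ValueError(f"series of length {n} too short for m={p.m}")
    sd = x.std()
    if sd == 0:
        raise DegenerateSeriesError("series has zero standard deviation")
    x = (x - x.mean()) / sd

    tm = _embed(x, p.m)          # N-m+1 templates
    tm1 = _embed(x, p.m + 1)     # N-m templates
    # phi(m): j over the first N-m templates, z over all N-m+1, z != j
    b = _strict_pair_count(tm[:-1], tm, p.r) - (n - p.m)   # remove self-pairs
    a = _strict_pair_count(tm1, tm1, p.r) - (n - p.m)
    if b == 0 or a == 0:
        raise UndefinedEntropyError(
            f"no template matches at m={p.m} (B={b}) or m+1 (A={a})"
        )
    return float(-np.log(a / b))


# ---------------------------------------------------------------------------
# Spatial heterogeneity index
# ---------------------------------------------------------------------------

def shi(trajectory: np.ndarray, p: ShiParams = ShiParams()) -> float:
    """Mean ln(d2/d1) over trajectory points with a valid neighbour pair.

    For each point n with n+step in range: the nearest neighbour j* by
    Euclidean distance (indices within the Theiler window of n excluded)
    must itself have j*+step in range, else n is skipped; d1 = |x(n)-x(j*)|,
    d2 = |x(n+step)-x(j*+step)|. Zero distances are skipped and counted.
    """
    x = np.atleast_2d(np.asarray(trajectory, dtype=float))
    n = x.shape[0]
    if n <= p.step + p.neighbor_exclusion + 1:
        raise ShiUndefinedError(f"trajectory of {n} points too short")

    terms: list[np.ndarray] = []
    chunk = 256
    for lo in range(0, n - p.step, chunk):
        hi = min(lo + chunk, n - p.step)
        d2mat = cdist(x[lo:hi], x, metric="sqeuclidean")
        rows = np.arange(lo, hi)
        for off in range(-p.neighbor_exclusion, p.neighbor_exclusion + 1):
            cols = rows + off
            ok = (cols >= 0) & (cols < n)
            d2mat[np.arange(hi - lo)[ok], cols[ok]] = np.inf
        j = np.argmin(d2mat, axis=1)
        dmin = d2mat[np.arange(hi - lo), j]
        valid = np.isfinite(dmin) & (j + p.step < n)
        i_ok, j_ok = rows[valid], j[valid]
        d1 = np.sqrt(dmin[valid])
        d2 = np.linalg.norm(x[i_ok + p.step] - x[j_ok + p.step], axis=1)
        keep = (d1 > 0) & (d2 > 0)
        terms.append(np.log(d2[keep] / d1[keep]))
    all_terms = np.concatenate(terms) if terms else np.empty(0)
    if all_terms.size == 0:
        raise ShiUndefinedError("no valid neighbour pairs")
    return float(np.mean(all_terms))


# ---------------------------------------------------------------------------
# Temporal heterogeneity index
# ---------------------------------------------------------------------------

def _decay_exponent(series: np.ndarray, p: ThiParams) -> int:
    """Integer lambda in 1..L minimizing the L1 distance between the one-sided
    magnitude spectrum (DC excluded) and f(w1)*exp(-decay_scale*lambda*k)."""
    mag = np.abs(np.fft.rfft(np.asarray(series, dtype=float)))[1:]
    if mag.size < 1 or not np.any(mag > 0):
        raise ThiUndefinedError("all-zero lead: spectrum has no support")
    return _fit_decay_to_spectrum(mag, p)


def _fit_decay_to_spectrum(mag: np.ndarray, p: ThiParams) -> int:
    big = mag.size
    k = np.arange(big)
    anchor = mag[0]
    best_lam, best_cost = 1, np.inf
    chunk = 256
    for lam0 in range(1, big + 1, chunk):
        lams = np.arange(lam0, min(lam0 + chunk, big + 1))
        model = anchor * np.exp(-p.decay_scale * lams[:, None] * k[None, :])
        costs = np.abs(mag[None, :] - model).sum(axis=1)
        i = int(np.argmin(costs))
        if costs[i] < best_cost:
            best_cost, best_lam = float(costs[i]), int(lams[i])
    return best_lam


def thi(vx: np.ndarray, vy: np.ndarray, vz: np.ndarray,
        p: ThiParams = ThiParams()) -> float:
    """RMS of the three per-lead decay exponents: sqrt((gx^2+gy^2+gz^2)/3)."""
    for s in (vx, vy, vz):
        if np.asarray(s).size < 8:
            raise ValueError("each lead series must have at least 8 samples")
    gammas = [_decay_exponent(s, p) for s in (vx, vy, vz)]
    return float(np.sqrt(np.mean(np.square(gammas, dtype=float))))


# ---------------------------------------------------------------------------
# Record-level extraction
# ---------------------------------------------------------------------------

def extract_features(
    ecg: MultiLeadRecord,
    vcg: VCGRecord,
    segs: STTSegmentSet,
    sampen: SampEnParams = SampEnParams(),
    shi_params: ShiParams = ShiParams(),
    thi_params: ThiParams = ThiParams(),
) -> FeatureVector:
    """All 17 features of one record; failures are flagged, not raised."""
    values: dict[str, float] = {}
    flags: dict[str, str] = {}

    def _try(key: str, fn):
        try:
            values[key] = float(fn())
        except Exception as exc:  # flagged, record excluded from modelling
            values[key] = float("nan")
            flags[key] = f"{type(exc).__name__}: {exc}"

    spliced_ecg = {}
    for lead in LEAD_ORDER:
        spliced_ecg[lead], _ = splice_stt(ecg.lead(lead), segs)
    spliced_vcg = {name: splice_stt(vcg.lead(name), segs)[0]
                   for name in ("Vx", "Vy", "Vz")}

    for lead in LEAD_ORDER:
        _try(f"S_{lead}", lambda lead=lead: sample_entropy(spliced_ecg[lead], sampen))
    for name in ("Vx", "Vy", "Vz"):
        _try(f"S_{name}", lambda name=name: sample_entropy(spliced_vcg[name], sampen))

    traj = np.column_stack([spliced_vcg["Vx"], spliced_vcg["Vy"], spliced_vcg["Vz"]])
    _try("SHI", lambda: shi(traj, shi_params))
    _try("THI", lambda: thi(spliced_vcg["Vx"], spliced_vcg["Vy"], spliced_vcg["Vz"],
                            thi_params))
    return FeatureVector(values=values, flags=flags)
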