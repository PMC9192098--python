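"""R-peak detection and per-beat ST-T delineation.

Delineation runs once per record on the RMS-across-leads signal; the
resulting sample intervals are shared by all ECG leads and by the derived
VCG (which is a linear combination of the same samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as _sig

from .errors import DelineationError, EmptySegmentSetError, InsufficientBeatsError
from .io import MultiLeadRecord


@dataclass(frozen=True)
class Beat:
    r_peak: int
    stt_start: int
    stt_end: int  # half-open [stt_start, stt_end)

    def __post_init__(self) -> None:
        if not self.r_peak < self.stt_start < self.stt_end:
            raise ValueError("require r_peak < stt_start < stt_end")


@dataclass
class STTSegmentSet:
    """Per-beat ST-T intervals of one record, shared across leads."""

    beats: list[Beat]
    fs: float
    record_id: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        for prev, cur in zip(self.beats, self.beats[1:]):
            if cur.stt_start < prev.stt_end or cur.r_peak <= prev.r_peak:
                raise ValueError("beats must be sorted and non-overlapping")
        lo, hi = 0.08 * self.fs, 0.6 * self.fs
        for b in self.beats:
            if not (lo <= b.stt_end - b.stt_start <= hi):
                raise ValueError(
                    f"ST-T duration {b.stt_end - b.stt_start} samples outside "
                    f"[80 ms, 600 ms] at fs={self.fs}"
                )

    def __len__(self) -> int:
        return len(self.beats)


# ---------------------------------------------------------------------------
# R-peak detection (Pan-Tompkins style)
# ---------------------------------------------------------------------------

def detect_r_peaks(lead: np.ndarray, fs: float) -> np.ndarray:
    """Detect R peaks on one (preprocessed) lead.

    Band-pass 5-15 Hz, differentiate, square, integrate over a 150 ms
    window, pick peaks with a 200 ms refractory period above an adaptive
    threshold, then refine each to the local |amplitude| extremum of the
    raw lead within +/-50 ms.
    """
    lead = np.asarray(lead, dtype=float)
    if lead.size < 2 * fs:
        raise InsufficientBeatsError("need at least 2 s of signal")
    sos = _sig.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = _sig.sosfiltfilt(sos, lead)
    feat = np.gradient(bp) ** 2
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(feat, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    cand, props = _sig.find_peaks(integ, distance=refractory)
    if cand.size < 3:
        raise InsufficientBeatsError(f"only {cand.size} candidate peaks")
    heights = integ[cand]
    # adaptive threshold: a fraction of the typical strong-peak height
    strong = np.sort(heights)[-max(3, heights.size // 2):]
    thr = 0.25 * np.median(strong)
    peaks = cand[heights >= thr]
    if peaks.size < 3:
        raise InsufficientBeatsError(f"only {peaks.size} peaks above threshold")

    # refine to the raw-lead extremum near each integrated peak
    half = int(round(0.050 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(lead.size, p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(lead[lo:hi]))))
    refined = np.unique(refined)
    # merge refinements that collapsed within the refractory period
    keep = [int(refined[0])]
    for p in refined[1:]:
        if p - keep[-1] >= refractory:
            keep.append(int(p))
        elif np.abs(lead[p]) > np.abs(lead[keep[-1]]):
            keep[-1] = int(p)
    if len(keep) < 3:
        raise InsufficientBeatsError(f"only {len(keep)} peaks after refinement")
    return np.asarray(keep, dtype=int)


# ---------------------------------------------------------------------------
# ST-T delineation
# ---------------------------------------------------------------------------

def _rms_signal(rec: MultiLeadRecord) -> np.ndarray:
    return np.sqrt(np.mean(rec.samples ** 2, axis=1))


def delineate_stt(
    rec: MultiLeadRecord,
    r_peaks: Sequence[int],
    st_onset_delay_s: float = 0.040,
    slope_fraction: float = 0.05,
) -> STTSegmentSet:
    """Locate per-beat (ST onset, T offset) intervals on the RMS signal.

    J point: first sample after R where the 40 ms slope magnitude of the
    RMS signal drops below ``slope_fraction`` of the beat's peak QRS slope,
    bounded to [R+30 ms, R+120 ms]. ST onset = J + 40 ms. T offset: tangent
    method after the T apex, bounded to [R+200 ms, R+min(600 ms, 0.7*RR)].
    Beats violating their bounds (or truncated by the record end) are
    dropped and counted.
    """
    r_peaks = np.sort(np.asarray(r_peaks, dtype=int))
    if r_peaks.size < 3:
        raise DelineationError("need at least 3 R peaks")
    fs = rec.fs
    rms = _rms_signal(rec)
    n = rms.size
    slope_win = max(1, int(round(0.040 * fs)))
    # centred 40 ms slope of the RMS signal
    kernel = np.array([1.0, -1.0])
    slope = np.convolve(rms, kernel, mode="same")
    slope = np.convolve(slope, np.ones(slope_win) / slope_win, mode="same") * fs

    rr = np.diff(r_peaks)
    med_rr = float(np.median(rr))

    beats: list[Beat] = []
    dropped = 0
    for k, r in enumerate(r_peaks):
        this_rr = float(rr[k]) if k < rr.size else med_rr
        j_lo = r + int(round(0.030 * fs))
        j_hi = r + int(round(0.120 * fs))
        end_bound = r + int(round(min(0.600, 0.7 * this_rr / fs) * fs))
        if end_bound >= n or j_hi >= n:
            dropped += 1
            continue
        qrs_lo = max(0, r - int(round(0.030 * fs)))
        peak_slope = np.max(np.abs(slope[qrs_lo:r + int(round(0.030 * fs)) + 1]))
        seg = np.abs(slope[j_lo:j_hi + 1])
        below = np.nonzero(seg < slope_fraction * peak_slope)[0]
        j = j_lo + int(below[0]) if below.size else j_hi
        stt_start = j + int(round(st_onset_delay_s * fs))

        t_lo = r + int(round(0.150 * fs))
        if t_lo >= end_bound:
            dropped += 1
            continue
        window = rms[t_lo:end_bound + 1]
        apex = t_lo + int(np.argmax(window))
        down = slope[apex:end_bound + 1]
        if down.size < 2:
            dropped += 1
            continue
        steep = apex + int(np.argmin(down))
        baseline = float(np.percentile(rms[t_lo:end_bound + 1], 5))
        s = slope[steep]
        if s < 0:
            t_off = steep + int(round((rms[steep] - baseline) / (-s) * fs))
        else:
            t_off = end_bound
        t_off = min(t_off, end_bound)
        t_off = max(t_off, r + int(round(0.200 * fs)))

        dur = t_off - stt_start
        if not (0.08 * fs <= dur <= 0.6 * fs) or t_off > n:
            dropped += 1
            continue
        if beats and stt_start < beats[-1].stt_end:
            dropped += 1
            continue
        beats.append(Beat(int(r), int(stt_start), int(t_off)))

    if len(beats) < 3:
        raise DelineationError(
            f"only {len(beats)} valid beats after delineation ({dropped} dropped)"
        )
    return STTSegmentSet(beats, fs=fs, record_id=rec.record_id, n_dropped=dropped)


def splice_stt(lead: np.ndarray, segs: STTSegmentSet) -> tuple[np.ndarray, list[int]]:
    """Concatenate per-beat ST-T windows of one lead.

    Returns (spliced series, boundary index list of length n_beats+1).
    """
    if len(segs) == 0:
        raise EmptySegmentSetError("no segments to splice")
    lead = np.asarray(lead, dtype=float)
    pieces = []
    bounds = [0]
    for b in segs.beats:
        if b.stt_end > lead.size:
            raise ValueError("segment extends beyond series")
        pieces.append(lead[b.stt_start:b.stt_end])
        bounds.append(bounds[-1] + (b.stt_end - b.stt_start))
    return np.concatenate(pieces), bounds
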