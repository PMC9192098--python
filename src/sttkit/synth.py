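"""Synthetic labelled 12-lead ECG records with controllable ST-T morphology.

Beats are sum-of-Gaussians PQRST templates placed on a 20 s, 1,000 Hz
canvas and scaled per lead by a fixed amplitude profile. The ischemic
preset deviates the ST level, inverts the T wave and adds a smooth
beat-to-beat repolarization perturbation confined to the ST-T window
(low-order random polynomial, so it survives wavelet denoising). All
outputs are pure functions of (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError
from .io import LEAD_ORDER, MultiLeadRecord
from .segment import Beat, STTSegmentSet

#: Per-lead amplitude scaling over the canonical 12-lead order
#: (I, II, III, AVR, AVL, AVF, V1..V6); mimics typical limb/precordial
#: proportions. Lead II is the unit reference.
LEAD_PROFILE = np.array([
    0.70, 1.00, 0.35, -0.85, 0.30, 0.65,
    -0.40, -0.20, 0.30, 0.90, 1.10, 0.80,
])
LEAD_PROFILE.setflags(write=False)


@dataclass(frozen=True)
class BeatTemplateParams:
    heart_rate: float = 70.0        # bpm
    p_amp: float = 0.12             # mV (lead-II reference, scaled by profile)
    q_amp: float = 0.08
    r_amp: float = 1.00
    s_amp: float = 0.20
    t_amp: float = 0.35
    st_deviation: float = 0.0       # mV offset of the ST level
    t_inversion: bool = False
    stt_jitter_sd: float = 0.0      # mV, beat-to-beat smooth ST-T perturbation
    rr_jitter_sd: float = 0.0       # s

    def __post_init__(self) -> None:
        if not 40.0 <= self.heart_rate <= 180.0:
            raise ConfigError("heart_rate must be in [40, 180] bpm")
        if self.stt_jitter_sd < 0 or self.rr_jitter_sd < 0:
            raise ConfigError("jitter SDs must be non-negative")


@dataclass(frozen=True)
class NoiseParams:
    baseline_amp: float = 0.0       # mV
    baseline_freq: float = 0.30     # Hz, must stay below the 0.67 Hz high-pass
    powerline_amp: float = 0.0      # mV at 50 Hz
    broadband_sd: float = 0.0       # mV

    def __post_init__(self) -> None:
        if min(self.baseline_amp, self.powerline_amp, self.broadband_sd) < 0:
            raise ConfigError("noise amplitudes must be non-negative")
        if not self.baseline_freq < 0.67:
            raise ConfigError("baseline_freq must be below 0.67 Hz")


#: Frozen presets; tuned once against the feature pipeline, then fixed.
#: The ischemic preset pairs ST depression with a flattened T wave and a
#: strictly larger beat-to-beat repolarization jitter than the healthy one.
HEALTHY_PRESET = BeatTemplateParams()
ISCHEMIC_PRESET = BeatTemplateParams(
    st_deviation=-0.10, t_amp=0.15, stt_jitter_sd=0.05,
)
DEFAULT_NOISE = NoiseParams(baseline_amp=0.05, powerline_amp=0.02, broadband_sd=0.05)
ZERO_NOISE = NoiseParams(baseline_amp=0.0, powerline_amp=0.0, broadband_sd=0.0)

# Template geometry (seconds relative to the R peak).
_PRE = 0.30          # template support before R
_J_DELAY = 0.045     # R -> J point
_ST_ONSET_DELAY = 0.040   # J -> ST onset
_T_CENTER = 0.300
_T_SIGMA = 0.050
_T_SUPPORT = 2.0     # truth T offset = tangent intercept of a Gaussian T: center + 2 sigma


def _timing_scale(heart_rate: float) -> float:
    """Bazett-style compression of repolarization timing at high rates."""
    rr = 60.0 / heart_rate
    return float(np.clip(math.sqrt(rr / (60.0 / 70.0)), 0.6, 1.15))


def generate_beat(params: BeatTemplateParams, fs: float) -> tuple[np.ndarray, dict]:
    """One PQRST template for all 12 leads.

    Returns (waveform of shape (n, 12), fiducials) where fiducials holds the
    template-relative sample indices ``r_peak``, ``st_onset`` (J + 40 ms)
    and ``t_offset`` (the tangent-method intercept of a Gaussian T wave,
    center + 2 sigma), plus ``j_point``.
    """
    if fs < 250:
        raise ConfigError("fs must be at least 250 Hz")
    s = _timing_scale(params.heart_rate)
    t_center = _T_CENTER * s
    t_sigma = _T_SIGMA * s
    t_off_rel = t_center + _T_SUPPORT * t_sigma
    t = np.arange(-_PRE, t_center + 4.0 * t_sigma, 1.0 / fs)

    t_sign = -1.0 if params.t_inversion else 1.0
    waves = [
        (-0.170, 0.025, params.p_amp),
        (-0.025, 0.010, -params.q_amp),
        (0.000, 0.012, params.r_amp),
        (0.025, 0.010, -params.s_amp),
        (t_center, t_sigma, t_sign * params.t_amp),
    ]
    base = np.zeros_like(t)
    for center, sigma, amp in waves:
        base += amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)

    # ST plateau: cosine ramp ending at the J point so the 80 ms post-J
    # window sits entirely at the commanded level, decaying into the T wave.
    if params.st_deviation != 0.0:
        j = _J_DELAY
        ramp_w, fall_w = 0.020, 0.050
        fall_at = t_center - 1.5 * t_sigma
        env = np.zeros_like(t)
        env[(t >= j) & (t < fall_at)] = 1.0
        up = (t >= j - ramp_w) & (t < j)
        env[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - (j - ramp_w)) / ramp_w))
        dn = (t >= fall_at) & (t < fall_at + fall_w)
        env[dn] = 0.5 * (1 + np.cos(np.pi * (t[dn] - fall_at) / fall_w))
        base += params.st_deviation * env

    wf = base[:, None] * LEAD_PROFILE[None, :]
    r_idx = int(round(_PRE * fs))
    fid = {
        "r_peak": r_idx,
        "j_point": r_idx + int(round(_J_DELAY * fs)),
        "st_onset": r_idx + int(round((_J_DELAY + _ST_ONSET_DELAY) * fs)),
        "t_offset": r_idx + int(round(t_off_rel * fs)),
    }
    return wf, fid


def _stt_perturbation(rng: np.random.Generator, length: int, sd: float) -> np.ndarray:
    """Smooth zero-mean perturbation: random cubic with cosine edge taper."""
    u = np.linspace(-1.0, 1.0, length)
    coef = rng.normal(size=4)
    p = coef[0] + coef[1] * u + coef[2] * (u ** 2) + coef[3] * (u ** 3)
    taper = np.ones(length)
    k = max(2, length // 5)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
    taper[:k] *= ramp
    taper[-k:] *= ramp[::-1]
    p = (p - p.mean()) * taper
    denom = p.std()
    return p * (sd / denom) if denom > 0 else np.zeros(length)


def generate_record(
    class_label: str,
    params: BeatTemplateParams | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
    fs: float = 1000.0,
    duration: float = 20.0,
    record_id: str | None = None,
) -> tuple[MultiLeadRecord, STTSegmentSet]:
    """A labelled 20 s, 12-lead record plus its ground-truth ST-T segments.

    ``class_label`` selects the preset ("healthy" | "ischemic") when
    ``params`` is None. The ground truth lists only beats whose full ST-T
    window lies inside the record.
    """
    if class_label not in ("healthy", "ischemic"):
        raise ConfigError(f"unknown class label {class_label!r}")
    if params is None:
        params = HEALTHY_PRESET if class_label == "healthy" else ISCHEMIC_PRESET
    if noise is None:
        noise = ZERO_NOISE
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    canvas = np.zeros((n, 12))

    template, fid = generate_beat(params, fs)
    rr = 60.0 / params.heart_rate
    rr_samples = rr * fs

    # R-peak times; integer-sample grid when jitter is zero so that every
    # beat is sample-identical.
    r_list: list[int] = []
    pos = 0.35 * fs
    while pos < n:
        r_list.append(int(round(pos)))
        step = round(rr_samples) if params.rr_jitter_sd == 0 else (
            rr_samples + rng.normal(0.0, params.rr_jitter_sd) * fs
        )
        pos += step

    beats: list[Beat] = []
    stt_lo = fid["st_onset"] - fid["r_peak"]
    stt_hi = fid["t_offset"] - fid["r_peak"]
    for r in r_list:
        start = r - fid["r_peak"]
        beat_wf = template
        if params.stt_jitter_sd > 0:
            pert = _stt_perturbation(rng, stt_hi - stt_lo, params.stt_jitter_sd)
            beat_wf = template.copy()
            sl = slice(fid["st_onset"], fid["t_offset"])
            beat_wf[sl] = beat_wf[sl] + pert[:, None] * LEAD_PROFILE[None, :]
        lo = max(0, start)
        hi = min(n, start + template.shape[0])
        if hi <= lo:
            continue
        canvas[lo:hi] += beat_wf[lo - start:hi - start]
        if start >= 0 and r + stt_hi <= n:
            beats.append(Beat(r, r + stt_lo, r + stt_hi))

    for lead in range(12):
        if noise.baseline_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            canvas[:, lead] += noise.baseline_amp * np.sin(
                2 * np.pi * noise.baseline_freq * np.arange(n) / fs + phase
            )
        if noise.powerline_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            canvas[:, lead] += noise.powerline_amp * np.sin(
                2 * np.pi * 50.0 * np.arange(n) / fs + phase
            )
        if noise.broadband_sd > 0:
            canvas[:, lead] += rng.normal(0.0, noise.broadband_sd, size=n)

    rid = record_id or f"synth-{class_label}-{seed}"
    rec = MultiLeadRecord(canvas, fs=fs, lead_names=LEAD_ORDER,
                          record_id=rid, label=class_label)
    truth = STTSegmentSet(beats, fs=fs, record_id=rid)
    return rec, truth


def generate_cohort(
    n_ischemic: int,
    n_healthy: int,
    seed: int = 0,
    noise: NoiseParams | None = None,
) -> list[tuple[MultiLeadRecord, STTSegmentSet]]:
    """Deterministic labelled cohort with mild within-class parameter spread."""
    if n_ischemic < 0 or n_healthy < 0:
        raise ConfigError("counts must be non-negative")
    if noise is None:
        noise = DEFAULT_NOISE
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_ischemic + n_healthy)
    out: list[tuple[MultiLeadRecord, STTSegmentSet]] = []
    for i, child in enumerate(children):
        label = "ischemic" if i < n_ischemic else "healthy"
        base = ISCHEMIC_PRESET if label == "ischemic" else HEALTHY_PRESET
        prng = np.random.default_rng(child)
        params = replace(
            base,
            heart_rate=float(np.clip(base.heart_rate + prng.uniform(-8, 8), 40, 180)),
            t_amp=base.t_amp * prng.uniform(0.85, 1.15),
            r_amp=base.r_amp * prng.uniform(0.9, 1.1),
            st_deviation=base.st_deviation * prng.uniform(0.7, 1.3),
            stt_jitter_sd=base.stt_jitter_sd * prng.uniform(0.8, 1.2),
        )
        rec_seed = int(prng.integers(0, 2 ** 31 - 1))
        idx = i if label == "ischemic" else i - n_ischemic
        rec, truth = generate_record(
            label, params=params, noise=noise, seed=rec_seed,
            record_id=f"synth-{label}-{idx:03d}",
        )
        out.append((rec, truth))
    return out
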