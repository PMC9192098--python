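"""Multi-lead record containers and I/O: WFDB (format 16), delimited text,
resampling, and feature-table persistence.

All amplitudes are in millivolts. Sample indices are 0-based and intervals
half-open. The canonical 12-lead order is fixed so that downstream code can
index leads positionally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .errors import LeadNotFoundError, ParseError, RecordTooShortError, SchemaError

#: Canonical 12-lead order used everywhere downstream.
LEAD_ORDER: tuple[str, ...] = (
    "I", "II", "III", "AVR", "AVL", "AVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: Canonical duration of an analysis window, seconds.
ANALYSIS_SECONDS = 20.0

#: Feature-table column order (17 features).
FEATURE_COLUMNS: tuple[str, ...] = (
    "S_I", "S_II", "S_III", "S_AVR", "S_AVL", "S_AVF",
    "S_V1", "S_V2", "S_V3", "S_V4", "S_V5", "S_V6",
    "S_Vx", "S_Vy", "S_Vz", "SHI", "THI",
)


def normalize_lead_name(name: str) -> str:
    """Map a lead label to its canonical spelling (case-insensitive).

    ``"avf" -> "AVF"``, ``"v6" -> "V6"``. Unknown labels are upper-cased
    but otherwise passed through, so non-standard channels survive I/O.
    """
    return name.strip().upper()


@dataclass
class MultiLeadRecord:
    """A uniformly sampled multi-lead ECG in mV."""

    samples: np.ndarray  # (n_samples, n_leads)
    fs: float
    lead_names: tuple[str, ...]
    record_id: str = ""
    label: str = "unknown"  # "ischemic" | "healthy" | "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (n_samples, n_leads)")
        self.lead_names = tuple(normalize_lead_name(n) for n in self.lead_names)
        if self.samples.shape[1] != len(self.lead_names):
            raise ValueError(
                f"{self.samples.shape[1]} columns but {len(self.lead_names)} lead names"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if np.isnan(self.samples).any():
            raise ValueError("samples contain NaN")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_leads(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def lead_index(self, name: str) -> int:
        key = normalize_lead_name(name)
        try:
            return self.lead_names.index(key)
        except ValueError:
            raise LeadNotFoundError(key) from None

    def lead(self, name: str) -> np.ndarray:
        """Return one lead as a 1-D view."""
        return self.samples[:, self.lead_index(name)]

    def is_canonical_length(self) -> bool:
        return self.n_samples == round(ANALYSIS_SECONDS * self.fs)

    def truncated_to_analysis_window(self) -> "MultiLeadRecord":
        """First 20 s of the record; error if shorter."""
        want = round(ANALYSIS_SECONDS * self.fs)
        if self.n_samples < want:
            raise RecordTooShortError(
                f"record {self.record_id!r} is {self.duration:.3f} s; "
                f"{ANALYSIS_SECONDS} s required"
            )
        if self.n_samples == want:
            return self
        return replace(self, samples=self.samples[:want].copy())


@dataclass
class VCGRecord:
    """A 3-lead orthogonal (X, Y, Z) signal derived from a MultiLeadRecord."""

    samples: np.ndarray  # (n_samples, 3)
    fs: float
    lead_names: tuple[str, str, str] = ("Vx", "Vy", "Vz")
    source_record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("VCG samples must be (n_samples, 3)")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def lead(self, name: str) -> np.ndarray:
        key = normalize_lead_name(name)
        names = tuple(normalize_lead_name(n) for n in self.lead_names)
        if key not in names:
            raise LeadNotFoundError(key)
        return self.samples[:, names.index(key)]


# ---------------------------------------------------------------------------
# WFDB format-16 reader/writer (self-contained; header + little-endian int16)
# ---------------------------------------------------------------------------

def read_wfdb_record(path: str | Path, channels: Sequence[str] | None = None) -> MultiLeadRecord:
    """Read a WFDB header/signal pair (format 16 only) into mV.

    ``path`` may point at the ``.hea`` file or be the extension-less record
    base name. ``channels`` optionally selects/reorders leads by name.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    rec_fields = lines[0].split()
    record_name = rec_fields[0]
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samp = int(rec_fields[3]) if len(rec_fields) > 3 else 0

    sig_lines = lines[1:1 + n_sig]
    if len(sig_lines) != n_sig:
        raise ParseError(f"header declares {n_sig} signals, found {len(sig_lines)}")

    dat_files: list[str] = []
    gains = np.empty(n_sig)
    baselines = np.zeros(n_sig)
    names: list[str] = []
    for i, ln in enumerate(sig_lines):
        parts = ln.split()
        dat_files.append(parts[0])
        fmt = parts[1].split("x")[0]
        if fmt != "16":
            raise ParseError(f"unsupported WFDB format {fmt!r} (only 16)", line=i + 2)
        gain_spec = parts[2] if len(parts) > 2 else "200"
        g = gain_spec.split("/")[0]
        if "(" in g:
            g, base = g.split("(")
            baselines[i] = float(base.rstrip(")"))
        gains[i] = float(g) if float(g) != 0 else 200.0
        # description = trailing tokens after the 8 standard fields, else index
        names.append(parts[8] if len(parts) > 8 else f"ch{i}")

    if len(set(dat_files)) != 1:
        raise ParseError("multi-file WFDB records are not supported")
    dat = hea.parent / dat_files[0]
    if not dat.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    if n_samp:
        raw = raw[: n_samp * n_sig]
    adc = raw.reshape(-1, n_sig).astype(float)
    mv = (adc - baselines) / gains

    rec = MultiLeadRecord(mv, fs=fs, lead_names=tuple(names), record_id=record_name)
    if channels is not None:
        idx = [rec.lead_index(c) for c in channels]
        rec = MultiLeadRecord(
            rec.samples[:, idx], fs=fs,
            lead_names=tuple(channels), record_id=record_name,
        )
    return rec


def write_wfdb_record(rec: MultiLeadRecord, path: str | Path, gain: float = 1000.0) -> None:
    """Write a record as a WFDB header + format-16 signal pair.

    Quantization is 1/gain mV (0.001 mV at the default 1000 ADU/mV).
    """
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".hea" else path
    adc = np.round(rec.samples * gain)
    if np.abs(adc).max(initial=0) > 32767:
        raise ValueError("signal exceeds int16 range at this gain")
    adc16 = adc.astype("<i2")
    with open(base.with_suffix(".hea"), "w") as fh:
        fh.write(f"{base.name} {rec.n_leads} {rec.fs:g} {rec.n_samples}\n")
        for i, name in enumerate(rec.lead_names):
            cksum = int(np.sum(adc16[:, i], dtype=np.int16))
            fh.write(
                f"{base.name}.dat 16 {gain:g}(0)/mV 16 0 "
                f"{int(adc16[0, i])} {cksum} 0 {name}\n"
            )
    adc16.tofile(base.with_suffix(".dat"))


# ---------------------------------------------------------------------------
# Delimited text records
# ---------------------------------------------------------------------------

def read_delimited_record(
    path: str | Path,
    fs: float,
    lead_names: Sequence[str] | None = None,
    record_id: str | None = None,
) -> MultiLeadRecord:
    """Read a numeric matrix (one column per lead) from CSV/TSV/whitespace text.

    A single header row naming the leads is consumed if present; when
    ``lead_names`` is None the header is required and supplies the names.
    """
    path = Path(path)
    rows: list[list[float]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = [c for c in line.replace(",", " ").replace("\t", " ").split() if c]
            if lineno == 1:
                try:
                    rows.append([float(c) for c in cells])
                    continue
                except ValueError:
                    header = [normalize_lead_name(c) for c in cells]
                    continue
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ParseError(f"non-numeric cell ({exc})", line=lineno) from None
    if not rows:
        raise ParseError("no data rows found")
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            first_bad = i + 1 + (1 if header else 0)
            raise ParseError(f"ragged row: {len(r)} cells, expected {width}", line=first_bad)
    if lead_names is None:
        if header is None:
            raise ParseError("no header row and no lead_names given")
        lead_names = header
    if len(lead_names) != width:
        raise ParseError(f"{width} columns but {len(lead_names)} lead names")
    return MultiLeadRecord(
        np.array(rows, dtype=float), fs=fs,
        lead_names=tuple(lead_names),
        record_id=record_id or path.stem,
    )


def write_delimited_record(rec: MultiLeadRecord, path: str | Path, delimiter: str = ",") -> None:
    """Write a record as delimited text with a lead-name header row."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(delimiter.join(rec.lead_names) + "\n")
        np.savetxt(fh, rec.samples, delimiter=delimiter, fmt="%.9g")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_record(rec: MultiLeadRecord, target_fs: float) -> MultiLeadRecord:
    """Polyphase resampling of every lead to ``target_fs``.

    Identity (the same object) when target_fs equals fs. Duration is
    preserved to within one output sample.
    """
    if not target_fs > 0:
        raise ValueError("target_fs must be positive")
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    out = _sig.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=0)
    return replace(rec, samples=out, fs=target_fs)


# ---------------------------------------------------------------------------
# Feature tables and evaluation reports
# ---------------------------------------------------------------------------

def write_feature_table(rows: Iterable[tuple[str, str, Sequence[float]]], path: str | Path) -> None:
    """Persist feature rows as CSV: record_id, label, then the 17 features."""
    recs = []
    for record_id, label, values in rows:
        values = list(values)
        if len(values) != len(FEATURE_COLUMNS):
            raise SchemaError(
                f"expected {len(FEATURE_COLUMNS)} features, got {len(values)}"
            )
        recs.append({"record_id": record_id, "label": label,
                     **dict(zip(FEATURE_COLUMNS, values))})
    df = pd.DataFrame(recs, columns=["record_id", "label", *FEATURE_COLUMNS])
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table, validating the schema.

    Returns a DataFrame with columns record_id, label, and the 17 features.
    """
    df = pd.read_csv(path)
    expected = ["record_id", "label", *FEATURE_COLUMNS]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in expected]
    if extra:
        raise SchemaError(f"feature table has unknown column(s): {', '.join(extra)}")
    return df[expected]


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
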