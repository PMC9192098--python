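"""Derivation of the 3-lead orthogonal VCG from 8 independent ECG leads.

The transform is a fixed 3x8 matrix applied per sample to leads
(I, II, V1..V6); lead III and the augmented limb leads are linear
combinations of I and II and are ignored.
"""

from __future__ import annotations

import numpy as np

from .io import MultiLeadRecord, VCGRecord

#: Input leads of the transform, in matrix-column order.
TRANSFORM_INPUT_LEADS: tuple[str, ...] = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: Rows Vx, Vy, Vz over columns I, II, V1..V6 (dimensionless).
LEAD_TRANSFORM_MATRIX = np.array([
    [0.38, -0.07, -0.13, 0.05, -0.01, 0.14, 0.06, 0.54],
    [-0.07, 0.93, 0.06, -0.02, -0.05, 0.06, -0.17, 0.13],
    [0.11, -0.23, -0.43, -0.06, -0.14, -0.20, -0.11, 0.31],
])
LEAD_TRANSFORM_MATRIX.setflags(write=False)


def ecg_to_vcg(rec: MultiLeadRecord) -> VCGRecord:
    """Project a 12-lead (or 8-lead) record onto orthogonal leads X, Y, Z.

    Raises LeadNotFoundError naming the first missing required lead.
    """
    cols = np.stack([rec.lead(name) for name in TRANSFORM_INPUT_LEADS], axis=1)
    xyz = cols @ LEAD_TRANSFORM_MATRIX.T
    return VCGRecord(xyz, fs=rec.fs, source_record_id=rec.record_id)
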