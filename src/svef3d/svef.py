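"""Segmental volume ejection fraction (SVEF) and the per-subject table.

Each of the 17 AHA segments gets its own end-diastolic and end-systolic
volume, defined as the largest and smallest values of that segment's own
volume-time curve — no common ED/ES time point is imposed, mirroring how the
curves are read off a segmental time-volume export.  Then

    SVEF = (EDV - ESV) / EDV * 100  (%)

and the global EF is computed by the identical rule on the summed
(total-cavity) curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aha import SEGMENT_LABELS
from .volumes import SegmentVolumeTrace, volume_curves

__all__ = ["SvefTable", "edv_esv", "svef", "build_svef_table"]


def edv_esv(trace: SegmentVolumeTrace) -> tuple[float, float]:
    """(EDV, ESV) of one volume-time curve: its max and min, in mL.

    Frame-wise extrema with no smoothing; ties resolve to the earliest frame
    (irrelevant for the values themselves).  Requires at least two points —
    a single sample has no diastole/systole to compare.
    """
    if len(trace) < 2:
        raise ValueError("need at least 2 time points to define EDV and ESV")
    return float(trace.volumes.max()), float(trace.volumes.min())


def svef(edv: float, esv: float) -> float:
    """(EDV - ESV) / EDV * 100, in percent.  EDV must be positive."""
    if edv <= 0:
        raise ValueError(f"degenerate segment: EDV must be positive, got {edv}")
    return (edv - esv) / edv * 100.0


@dataclass(frozen=True)
class SvefTable:
    """17 segmental ejection fractions plus the global EF for one subject."""

    subject_id: str
    svef: dict[int, float]
    global_ef: float
    edv: dict[int, float] = field(default_factory=dict)
    esv: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.svef) != set(SEGMENT_LABELS):
            missing = sorted(set(SEGMENT_LABELS) - set(self.svef))
            raise ValueError(f"SVEF table must cover all 17 segments; missing {missing}")

    def to_frame(self) -> pd.DataFrame:
        """One row per segment: subject, segment_id, label, edv_ml, esv_ml,
        svef_pct, global_ef_pct."""
        return pd.DataFrame(
            {
                "subject": self.subject_id,
                "segment_id": list(SEGMENT_LABELS),
                "label": [SEGMENT_LABELS[s] for s in SEGMENT_LABELS],
                "edv_ml": [self.edv.get(s, np.nan) for s in SEGMENT_LABELS],
                "esv_ml": [self.esv.get(s, np.nan) for s in SEGMENT_LABELS],
                "svef_pct": [self.svef[s] for s in SEGMENT_LABELS],
                "global_ef_pct": self.global_ef,
            }
        )

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "svef": {str(k): v for k, v in self.svef.items()},
            "global_ef": self.global_ef,
            "edv": {str(k): v for k, v in self.edv.items()},
            "esv": {str(k): v for k, v in self.esv.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SvefTable":
        return cls(
            subject_id=d["subject_id"],
            svef={int(k): float(v) for k, v in d["svef"].items()},
            global_ef=float(d["global_ef"]),
            edv={int(k): float(v) for k, v in d.get("edv", {}).items()},
            esv={int(k): float(v) for k, v in d.get("esv", {}).items()},
        )


def build_svef_table(
    source,
    total: SegmentVolumeTrace | None = None,
    subject_id: str = "phantom",
) -> SvefTable:
    """Assemble the SVEF table from a mesh sequence or precomputed curves.

    ``source`` is either a MeshSequence (curves are computed here) or a
    ``{segment_id: SegmentVolumeTrace}`` mapping, in which case ``total``
    may be given too (otherwise it is recomputed as the per-frame sum).
    """
    if hasattr(source, "frames"):
        traces, total = volume_curves(source)
    else:
        traces = dict(source)
        missing = sorted(set(SEGMENT_LABELS) - set(traces))
        if missing:
            raise ValueError(f"missing segment traces: {missing}")
        if total is None:
            t0 = traces[1]
            total = SegmentVolumeTrace(
                0, t0.times, np.sum([traces[s].volumes for s in SEGMENT_LABELS], axis=0)
            )

    edv, esv, ef = {}, {}, {}
    for sid in SEGMENT_LABELS:
        edv[sid], esv[sid] = edv_esv(traces[sid])
        ef[sid] = svef(edv[sid], esv[sid])
    g_edv, g_esv = edv_esv(total)
    return SvefTable(subject_id=subject_id, svef=ef, global_ef=svef(g_edv, g_esv), edv=edv, esv=esv)
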