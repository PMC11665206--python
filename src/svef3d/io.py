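"""File formats and packaged reference tables.

The canonical interchange format for segmental curves is a plain CSV with
header ``time_s, seg01, ..., seg17, total`` (UTF-8, decimal point, comma
separator) — the open equivalent of the spreadsheet export a clinical
workstation produces for segmental time-volume data.  Meshes are written as
ASCII OFF or PLY, one file per frame, with a JSON manifest carrying times,
landmarks, ground truth and the generating configuration.

Packaged reference tables (loaded with the ``fixture_*`` helpers):

- ``wall_motion_counts.csv`` — per-segment counts of the 2DE wall-motion
  reading in a 33-subject ischemic cohort (561 segments), in AHA column
  order seg01..seg17.  The source table lists walls in the order AS, A, AL,
  IL, I, IS per ring (then apical A, L, I, S, apical cap); the mapping to
  AHA ids is basal AS,A,AL,IL,I,IS -> 2,1,6,5,4,3, mid -> +6, apical
  A,L,I,S -> 13,16,15,14, cap -> 17.
- ``svef_group_moments.json`` — segmental-EF group moments for normal vs
  abnormal segments, the generator of the binormal ROC simulation.
- ``culprit_confusion.csv`` — 3x3 culprit-artery cross-tabulation of the
  volume-derived bull's-eye reading against the 2DE reference.
- ``territories.json`` — the typical ASE/EACVI coronary territory templates.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import ConfusionMatrix
from .aha import SEGMENT_LABELS
from .phantom import MeshFrame, MeshSequence
from .volumes import SegmentVolumeTrace

__all__ = [
    "write_volume_curves",
    "read_volume_curves",
    "write_off",
    "write_ply",
    "write_mesh_sequence",
    "fixture_wall_motion_counts",
    "fixture_table2_counts",
    "fixture_svef_moments",
    "fixture_confusion_matrix",
    "fixture_territories",
]

_SEG_COLS = [f"seg{j:02d}" for j in range(1, 18)]


def _data_path(name: str):
    return resources.files("svef3d.data").joinpath(name)


# ---------------------------------------------------------------------------
# volume-curve CSV dialect


def write_volume_curves(path, traces: dict[int, SegmentVolumeTrace], total: SegmentVolumeTrace) -> None:
    """Write the 17 segmental curves and the total to the canonical CSV."""
    df = pd.DataFrame({"time_s": total.times})
    for sid in SEGMENT_LABELS:
        df[f"seg{sid:02d}"] = traces[sid].volumes
    df["total"] = total.volumes
    df.to_csv(path, index=False)


def read_volume_curves(path) -> tuple[dict[int, SegmentVolumeTrace], SegmentVolumeTrace]:
    """Read curves from the canonical CSV dialect.

    Accepts 18 columns (``time_s`` + 17 segments; total recomputed as row
    sums) or 19 (with ``total``).  Errors name the offending column or row.
    """
    df = pd.read_csv(path)
    missing = [c for c in ["time_s", *_SEG_COLS] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in {"time_s", "total", *_SEG_COLS}]
    if extra:
        raise ValueError(f"{path}: unexpected column(s) {extra}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"{path}: non-numeric or missing value in column {col!r}, data row {row}")
    times = df["time_s"].to_numpy(float)
    steps = np.diff(times)
    if np.any(steps <= 0):
        row = int(np.flatnonzero(steps <= 0)[0]) + 1
        raise ValueError(f"{path}: time_s not strictly increasing at data row {row}")
    traces = {
        sid: SegmentVolumeTrace(sid, times, df[f"seg{sid:02d}"].to_numpy(float))
        for sid in SEGMENT_LABELS
    }
    if "total" in df.columns:
        total_v = df["total"].to_numpy(float)
    else:
        total_v = df[_SEG_COLS].to_numpy(float).sum(axis=1)
    return traces, SegmentVolumeTrace(0, times, total_v)


# ---------------------------------------------------------------------------
# ASCII mesh writers


def write_off(path, frame: MeshFrame) -> None:
    v, f = frame.vertices, frame.faces
    with open(path, "w") as fh:
        fh.write(f"OFF\n{len(v)} {len(f)} 0\n")
        for p in v:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        for tri in f:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def write_ply(path, frame: MeshFrame) -> None:
    v, f = frame.vertices, frame.faces
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {len(v)}\n"
            "property float x\nproperty float y\nproperty float z\n"
            f"element face {len(f)}\n"
            "property list uchar int vertex_indices\nend_header\n"
        )
        for p in v:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        for tri in f:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def write_mesh_sequence(out_dir, seq: MeshSequence, fmt: str = "off") -> Path:
    """Write one mesh file per frame plus ``manifest.json``; returns the dir."""
    from dataclasses import asdict

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    writer = {"off": write_off, "ply": write_ply}[fmt]
    names = []
    for k, frame in enumerate(seq.frames):
        name = f"frame_{k:03d}.{fmt}"
        writer(out / name, frame)
        names.append(name)
    cfg = None
    if seq.config is not None:
        cfg = asdict(seq.config)
        if not isinstance(cfg["rwma_territory"], str):
            cfg["rwma_territory"] = sorted(cfg["rwma_territory"])
    manifest = {
        "format": fmt,
        "frames": names,
        "times_s": seq.times.tolist(),
        "landmarks": {
            "apex_point": seq.axis_frame.apex_point.tolist(),
            "annulus_points": seq.axis_frame.annulus_points.tolist(),
            "mid_septum_point": seq.axis_frame.mid_septum_point.tolist(),
        },
        "ground_truth_severity": {str(k): v for k, v in seq.ground_truth.items()},
        "config": cfg,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# packaged reference tables


def fixture_wall_motion_counts() -> pd.DataFrame:
    """Per-segment wall-motion-score counts, rows = score groups."""
    with resources.as_file(_data_path("wall_motion_counts.csv")) as p:
        return pd.read_csv(p, index_col=0)


def fixture_table2_counts() -> dict[str, int]:
    """Total segment count per wall-motion class (sums of the packaged grid)."""
    grid = fixture_wall_motion_counts()
    return {group: int(grid.loc[group].sum()) for group in grid.index}


def fixture_svef_moments() -> dict:
    """Normal/abnormal segmental-EF group moments (n, mean, sd)."""
    d = json.loads(_data_path("svef_group_moments.json").read_text())
    d.pop("comment", None)
    return d


def fixture_confusion_matrix() -> ConfusionMatrix:
    """Culprit-artery confusion matrix (volume-derived reading vs 2DE)."""
    with resources.as_file(_data_path("culprit_confusion.csv")) as p:
        df = pd.read_csv(p, index_col=0)
    return ConfusionMatrix(df.to_numpy(np.int64), tuple(df.index))


def fixture_territories() -> dict[str, frozenset[int]]:
    d = json.loads(_data_path("territories.json").read_text())
    return {k: frozenset(v) for k, v in d.items()}


def load_territory_file(path) -> dict[str, frozenset[int]]:
    """User-supplied territory template JSON: {artery: [segment ids]}.

    The three sets must be disjoint and cover all 17 segments.
    """
    d = json.loads(Path(path).read_text())
    tpl = {k: frozenset(int(s) for s in v) for k, v in d.items()}
    allseg = [s for v in tpl.values() for s in v]
    if len(allseg) != len(set(allseg)) or set(allseg) != set(SEGMENT_LABELS):
        raise ValueError(f"{path}: territories must be disjoint and cover segments 1-17")
    return tpl
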