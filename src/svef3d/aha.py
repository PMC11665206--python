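"""17-segment AHA model of the left ventricle and coronary territory templates.

The LV surface is addressed in a prolate coordinate pair derived from the
landmark set used to initialise the analysis: four mitral-annular points, an
apical point and a mid-septal point.  ``u`` is the normalised position along
the long axis (0 at the annulus plane, 1 at the apex) and ``theta`` is the
circumferential angle about that axis in degrees.

Angle convention
----------------
``theta`` is measured right-handed about the annulus-to-apex axis and anchored
on the mid-septal landmark, which maps to ``theta = 270`` by a fixed offset.
Under this convention the anterior wall is centred on ``theta = 90``, the
lateral wall on ``theta = 180`` and the septum straddles ``theta = 0/360``.
Basal and mid rings are split into six 60° sectors with boundaries on
multiples of 60°; the apical ring into four 90° sectors with boundaries on
45° + k·90° so that the apical anterior segment is centred on the anterior
direction.  The offset is configurable for other display conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SEGMENT_LABELS",
    "LVAxisFrame",
    "FacetSegmentMap",
    "territory_segments",
    "TERRITORIES",
    "build_axis_coordinates",
    "assign_segments",
    "segment_of",
]

#: AHA segment id -> name.  1–6 basal, 7–12 mid, 13–16 apical, 17 apical cap.
SEGMENT_LABELS: dict[int, str] = {
    1: "basal anterior",
    2: "basal anteroseptal",
    3: "basal inferoseptal",
    4: "basal inferior",
    5: "basal inferolateral",
    6: "basal anterolateral",
    7: "mid anterior",
    8: "mid anteroseptal",
    9: "mid inferoseptal",
    10: "mid inferior",
    11: "mid inferolateral",
    12: "mid anterolateral",
    13: "apical anterior",
    14: "apical septal",
    15: "apical inferior",
    16: "apical lateral",
    17: "apex",
}

#: Typical coronary artery distribution (ASE/EACVI 17-segment assignment).
TERRITORIES: dict[str, frozenset[int]] = {
    "LAD": frozenset({1, 2, 7, 8, 13, 14, 17}),
    "RCA": frozenset({3, 4, 9, 10, 15}),
    "LCX": frozenset({5, 6, 11, 12, 16}),
}

# 60° sector index (theta // 60) -> basal segment id; mid = basal + 6.
_BASAL_BY_SECTOR = (2, 1, 6, 5, 4, 3)
# 90° sector index ((theta - 45) // 90 mod 4) -> apical segment id.
_APICAL_BY_SECTOR = (13, 16, 15, 14)

#: Default longitudinal fraction where the apical segments end and the cap begins.
U_CAP = 0.85


def territory_segments(artery: str, templates: dict[str, frozenset[int]] | None = None) -> frozenset[int]:
    """Return the segment set supplied by *artery* (``LAD``, ``LCX`` or ``RCA``).

    ``templates`` overrides the default typical distribution, e.g. for
    dominance variants loaded from a user configuration file.
    """
    tpl = TERRITORIES if templates is None else templates
    try:
        return frozenset(tpl[artery])
    except KeyError:
        raise KeyError(f"unknown artery {artery!r}; expected one of {sorted(tpl)}") from None


@dataclass(frozen=True)
class LVAxisFrame:
    """Landmark frame fixing the long axis and the circumferential origin.

    Parameters
    ----------
    apex_point : (3,) array, mm
    annulus_points : (4, 3) array, mm
        Four points on the mitral annulus; their centroid defines the basal
        end of the long axis.
    mid_septum_point : (3,) array, mm
        A point on the mid interventricular septum, off the long axis; it
        anchors ``theta`` (maps to 270°).
    """

    apex_point: np.ndarray
    annulus_points: np.ndarray
    mid_septum_point: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "apex_point", np.asarray(self.apex_point, float))
        object.__setattr__(self, "annulus_points", np.asarray(self.annulus_points, float))
        object.__setattr__(self, "mid_septum_point", np.asarray(self.mid_septum_point, float))
        if self.annulus_points.shape != (4, 3):
            raise ValueError("annulus_points must be a (4, 3) array")
        o, d, L = self._axis()
        if L <= 0:
            raise ValueError("apex lies on the annulus plane: degenerate long axis")
        p = self.mid_septum_point - o
        if np.linalg.norm(p - (p @ d) * d) < 1e-9:
            raise ValueError("mid_septum_point lies on the long axis")

    def _axis(self) -> tuple[np.ndarray, np.ndarray, float]:
        origin = self.annulus_points.mean(axis=0)
        v = self.apex_point - origin
        length = float(np.linalg.norm(v))
        return origin, (v / length if length > 0 else v), length

    @property
    def origin(self) -> np.ndarray:
        """Annulus centroid — the basal end of the long axis (u = 0)."""
        return self._axis()[0]

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from annulus centroid to apex."""
        return self._axis()[1]

    @property
    def length(self) -> float:
        return self._axis()[2]

    @property
    def midpoint(self) -> np.ndarray:
        """Axis midpoint, the common apex of the segmental volume tetrahedra."""
        o, d, L = self._axis()
        return o + 0.5 * L * d


def build_axis_coordinates(
    vertices: np.ndarray, axis: LVAxisFrame, theta_offset: float = 270.0
) -> tuple[np.ndarray, np.ndarray]:
    """Map points to (u, theta) in the landmark frame.

    u is the projection onto the long axis normalised so the annulus plane is
    0 and the apex 1 (clipped to [0, 1]); theta in degrees follows the module
    convention (the mid-septal landmark direction maps to ``theta_offset``).
    """
    pts = np.atleast_2d(np.asarray(vertices, float))
    o, d, L = axis._axis()
    rel = pts - o
    u = np.clip((rel @ d) / L, 0.0, 1.0)

    s = axis.mid_septum_point - o
    s -= (s @ d) * d
    e1 = s / np.linalg.norm(s)
    e2 = np.cross(d, e1)
    phi = np.degrees(np.arctan2(rel @ e2, rel @ e1))  # angle from septum dir
    theta = np.mod(phi + theta_offset, 360.0)
    return u, theta


def segment_of(u: float | np.ndarray, theta: float | np.ndarray, u_cap: float = U_CAP) -> np.ndarray:
    """AHA segment id(s) for coordinates (u, theta).

    Longitudinal bands: basal u < 1/3, mid 1/3 <= u < 2/3, apical
    2/3 <= u < u_cap, cap u >= u_cap.
    """
    u = np.asarray(u, float)
    theta = np.mod(np.asarray(theta, float), 360.0)
    seg = np.full(u.shape, 17, dtype=int)

    six = np.take(_BASAL_BY_SECTOR, np.minimum((theta / 60.0).astype(int), 5))
    four = np.take(_APICAL_BY_SECTOR, (((theta - 45.0) % 360.0) / 90.0).astype(int))

    basal = u < 1.0 / 3.0
    mid = (u >= 1.0 / 3.0) & (u < 2.0 / 3.0)
    apical = (u >= 2.0 / 3.0) & (u < u_cap)
    seg[basal] = six[basal]
    seg[mid] = six[mid] + 6
    seg[apical] = four[apical]
    return seg


@dataclass(frozen=True)
class FacetSegmentMap:
    """Per-face AHA segment assignment of a triangulated LV surface.

    ``segment`` holds one primary segment id per face (centroid rule: the
    face belongs to the segment containing its centroid, so the face sets
    partition the surface exactly).  ``weights``, present only when
    area-weighted boundary splitting was requested, maps face index ->
    {segment id: weight} with weights summing to 1 per face.
    """

    segment: np.ndarray
    weights: dict[int, dict[int, float]] | None = None

    def faces_of(self, segment_id: int) -> np.ndarray:
        return np.flatnonzero(self.segment == segment_id)


def assign_segments(
    frame,
    axis: LVAxisFrame,
    u_cap: float = U_CAP,
    theta_offset: float = 270.0,
    split_boundary_faces: bool = False,
) -> FacetSegmentMap:
    """Assign every face of a mesh frame to one of the 17 AHA segments.

    The default centroid rule gives an exact partition of the face set.
    With ``split_boundary_faces`` faces whose vertices land in different
    segments additionally carry fractional weights, estimated by sampling
    the face interior; the primary assignment stays the centroid's segment.
    """
    verts = frame.vertices
    faces = frame.faces
    centroids = verts[faces].mean(axis=1)
    u, theta = build_axis_coordinates(centroids, axis, theta_offset)
    seg = segment_of(u, theta, u_cap)

    weights = None
    if split_boundary_faces:
        uu, tt = build_axis_coordinates(verts, axis, theta_offset)
        vseg = segment_of(uu, tt, u_cap)
        weights = {}
        # barycentric sample grid, reused for every straddling face
        bary = np.array(
            [(i, j, 16 - i - j) for i in range(17) for j in range(17 - i)], float
        ) / 16.0
        for fi in np.flatnonzero(np.any(vseg[faces] != seg[:, None], axis=1)):
            pts = bary @ verts[faces[fi]]
            su, st = build_axis_coordinates(pts, axis, theta_offset)
            ids, counts = np.unique(segment_of(su, st, u_cap), return_counts=True)
            weights[int(fi)] = {int(i): float(c) / len(bary) for i, c in zip(ids, counts)}
    return FacetSegmentMap(segment=seg, weights=weights)
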