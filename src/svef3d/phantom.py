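"""Synthetic deforming LV endocardial meshes with known regional contraction.

The phantom stands in for a transthoracic 3D full-volume acquisition: a
closed, consistently oriented triangle mesh of the endocardial surface per
frame over one cardiac cycle, together with the landmark frame (four annular
points, apex, mid-septum) that real analyses are initialised with and a
ground-truth severity per AHA segment.

Shape model: a truncated prolate spheroid (half-ellipsoid of base radius
``base_radius`` and height ``long_axis_length``) closed at the mitral-annulus
plane by a flat disc.  Contraction moves vertices radially toward the long
axis,

    r(theta, z, t) = R(z) * (1 - A * s(theta, u) * g(t)),

with ``A`` the peak fractional radial contraction, ``g`` a half-sine systolic
waveform over the cycle (g(0) = g(T) = 0, peak 1 at mid-cycle) and ``s`` the
local severity: ``rwma_severity`` inside the configured coronary territory's
segments, 1 elsewhere, blended across sector borders by a cosine taper.
Because only radii scale, a uniform phantom's cavity volume obeys
V(t) = V_ED * (1 - A*g(t))**2, giving the closed-form global ejection
fraction 1 - (1 - A)**2 used as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aha import LVAxisFrame, SEGMENT_LABELS, segment_of, territory_segments

__all__ = [
    "PhantomConfig",
    "MeshFrame",
    "MeshSequence",
    "SvefPopulationSpec",
    "generate_phantom",
    "sample_svef_population",
]


@dataclass(frozen=True)
class MeshFrame:
    """One time point of the endocardial surface (vertices mm, seconds)."""

    vertices: np.ndarray
    faces: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", np.asarray(self.vertices, float))
        object.__setattr__(self, "faces", np.asarray(self.faces, np.int64))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3) vertex-index triples")


@dataclass(frozen=True)
class MeshSequence:
    """Time-ordered mesh frames sharing one topology, plus ground truth."""

    frames: tuple[MeshFrame, ...]
    axis_frame: LVAxisFrame
    ground_truth: dict[int, float] = field(default_factory=dict)
    config: "PhantomConfig | None" = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "frames", tuple(self.frames))
        if not self.frames:
            raise ValueError("empty sequence")
        f0 = self.frames[0].faces
        for f in self.frames[1:]:
            if f.faces.shape != f0.shape or not np.array_equal(f.faces, f0):
                raise ValueError("face topology must be identical across frames")
        times = self.times
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def __len__(self) -> int:
        return len(self.frames)


_TERRITORY_CHOICES = ("none", "LAD", "LCX", "RCA")


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the deforming-LV phantom.

    Defaults describe a plausible adult LV imaged at the mean full-volume
    frame rate of 17 Hz over a 1-second cycle: base radius 25 mm, long axis
    80 mm, peak radial contraction 0.30 (global EF ~51%).

    rwma_territory may be ``"none"``, an artery name (``LAD``/``LCX``/``RCA``)
    or an explicit set of AHA segment ids; ``rwma_severity`` multiplies the
    local contraction there (1 normal, 0 akinetic).  ``taper_deg`` is the
    angular width of the cosine blend at territory borders (0 = hard edges).
    """

    base_radius: float = 25.0
    long_axis_length: float = 80.0
    n_circumferential: int = 48
    n_longitudinal: int = 32
    n_frames: int = 17
    frame_rate: float = 17.0
    global_amplitude: float = 0.30
    rwma_territory: str | frozenset[int] = "none"
    rwma_severity: float = 1.0
    noise_sd: float = 0.0
    taper_deg: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius <= 0 or self.long_axis_length <= 0:
            raise ValueError("base_radius and long_axis_length must be positive")
        if self.n_circumferential < 12 or self.n_circumferential % 12:
            raise ValueError("n_circumferential must be >= 12 and divisible by 12")
        if self.n_longitudinal < 2:
            raise ValueError("n_longitudinal must be >= 2")
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not 0 < self.global_amplitude < 1:
            raise ValueError("global_amplitude must lie in (0, 1)")
        if not 0 <= self.rwma_severity <= 1:
            raise ValueError("rwma_severity must lie in [0, 1]")
        if self.noise_sd < 0 or self.taper_deg < 0:
            raise ValueError("noise_sd and taper_deg must be non-negative")
        self.abnormal_segments()  # validates the territory name

    def abnormal_segments(self) -> frozenset[int]:
        """Segment ids carrying the configured wall-motion abnormality."""
        t = self.rwma_territory
        if isinstance(t, str):
            if t == "none":
                return frozenset()
            if t not in _TERRITORY_CHOICES:
                raise ValueError(f"unknown territory {t!r}; expected one of {_TERRITORY_CHOICES}")
            return territory_segments(t)
        segs = frozenset(int(s) for s in t)
        if not segs <= set(SEGMENT_LABELS):
            raise ValueError("explicit segment set must be within 1..17")
        return segs


def _base_surface(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Reference (end-diastolic) geometry in cylindrical form.

    Returns ring radii R (n_long,), ring heights z (n_long,), column azimuths
    phi (n_circ,) in degrees, and the shared face array.  Rings are sampled
    uniformly in the ellipse's eccentric angle so facet size stays roughly
    even from base to apex.
    """
    nc, nl = cfg.n_circumferential, cfg.n_longitudinal
    psi = 0.5 * np.pi * np.arange(nl) / nl
    z = cfg.long_axis_length * np.sin(psi)
    R = cfg.base_radius * np.cos(psi)
    phi = 360.0 * np.arange(nc) / nc

    apex = nl * nc          # vertex indices of apex and base-disc centre
    center = nl * nc + 1

    faces = []
    for j in range(nl - 1):
        a = j * nc + np.arange(nc)
        b = j * nc + (np.arange(nc) + 1) % nc
        c, d = b + nc, a + nc
        faces.append(np.column_stack([a, b, c]))
        faces.append(np.column_stack([a, c, d]))
    top = (nl - 1) * nc + np.arange(nc)
    top_next = (nl - 1) * nc + (np.arange(nc) + 1) % nc
    faces.append(np.column_stack([top, top_next, np.full(nc, apex)]))
    bot = np.arange(nc)
    bot_next = (np.arange(nc) + 1) % nc
    faces.append(np.column_stack([np.full(nc, center), bot_next, bot]))
    return R, z, phi, np.vstack(faces)


def _severity_field(cfg: PhantomConfig, u_rings: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-(ring, column) contraction multiplier with optional angular taper.

    After sampling the per-segment severity at each vertex, the field is
    eroded by one vertex (minimum over the 3x3 index neighbourhood): a
    vertex on the border of an abnormal region moves with the weaker side,
    the discrete analogue of infarct-border tethering.  Without this, faces
    inside an akinetic segment would share moving vertices with normal
    neighbours and the segment would never be truly motionless.
    """
    abnormal = cfg.abnormal_segments()
    seg = segment_of(u_rings[:, None] * np.ones_like(phi)[None, :], np.tile(phi, (len(u_rings), 1)))
    s = np.where(np.isin(seg, list(abnormal) or [0]), cfg.rwma_severity, 1.0)
    if abnormal and cfg.rwma_severity < 1.0:
        rows = [np.clip(np.arange(len(u_rings)) + dr, 0, len(u_rings) - 1) for dr in (-1, 0, 1)]
        s = np.minimum.reduce([
            np.roll(s[r, :], dc, axis=1) for r in rows for dc in (-1, 0, 1)
        ])
    if cfg.taper_deg > 0 and abnormal:
        step = 360.0 / cfg.n_circumferential
        half = max(int(round(cfg.taper_deg / (2 * step))), 0)
        if half:
            offsets = np.arange(-half, half + 1)
            kernel = 0.5 * (1 + np.cos(np.pi * offsets / (half + 1)))
            kernel /= kernel.sum()
            idx = (np.arange(cfg.n_circumferential)[None, :] + offsets[:, None]) % cfg.n_circumferential
            s = np.einsum("k,rkc->rc", kernel, s[:, idx])
    return s


def generate_phantom(config: PhantomConfig) -> MeshSequence:
    """Build the deforming phantom sequence described by *config*.

    Deterministic for a given config (vertex jitter, if any, is drawn from a
    generator seeded with ``config.seed``).  Motion is purely radial, so the
    apex vertex and the base-disc centre stay fixed between frames.
    """
    cfg = config
    R, z, phi, faces = _base_surface(cfg)
    nc, nl = cfg.n_circumferential, cfg.n_longitudinal
    L = cfg.long_axis_length
    u_rings = z / L
    sev = _severity_field(cfg, u_rings, phi)

    cphi = np.cos(np.radians(phi))
    sphi = np.sin(np.radians(phi))
    rng = np.random.default_rng(cfg.seed)

    times = np.arange(cfg.n_frames) / cfg.frame_rate
    T = times[-1]
    g = np.sin(np.pi * times / T)

    abnormal = cfg.abnormal_segments()
    ground_truth = {sid: (cfg.rwma_severity if sid in abnormal else 1.0) for sid in SEGMENT_LABELS}

    frames = []
    for t, gt in zip(times, g):
        r = R[:, None] * (1.0 - cfg.global_amplitude * sev * gt)  # (nl, nc)
        verts = np.empty((nl * nc + 2, 3))
        verts[: nl * nc, 0] = (r * cphi[None, :]).ravel()
        verts[: nl * nc, 1] = (r * sphi[None, :]).ravel()
        verts[: nl * nc, 2] = np.repeat(z, nc)
        verts[nl * nc] = (0.0, 0.0, L)      # apex
        verts[nl * nc + 1] = (0.0, 0.0, 0.0)  # base-disc centre
        if cfg.noise_sd > 0:
            verts = verts + rng.normal(0.0, cfg.noise_sd, verts.shape)
        frames.append(MeshFrame(vertices=verts, faces=faces, time=float(t)))

    k = np.arange(4)
    annulus = np.column_stack(
        [cfg.base_radius * np.cos(k * np.pi / 2), cfg.base_radius * np.sin(k * np.pi / 2), np.zeros(4)]
    )
    axis = LVAxisFrame(
        apex_point=np.array([0.0, 0.0, L]),
        annulus_points=annulus,
        # placed so theta == raw azimuth under the 270-degree anchor convention
        mid_septum_point=np.array([0.0, -cfg.base_radius, 0.0]),
    )
    return MeshSequence(frames=tuple(frames), axis_frame=axis, ground_truth=ground_truth, config=cfg)


@dataclass(frozen=True)
class SvefPopulationSpec:
    """Two-Gaussian model of segmental EF scores in normal vs abnormal walls.

    Defaults are the observed group moments for 320 normal segments
    (52.7 +/- 15.0 %) and 241 abnormal (hypokinetic + akinetic pooled)
    segments (35.5 +/- 14.4 %).
    """

    n_normal: int = 320
    mean_normal: float = 52.7
    sd_normal: float = 15.0
    n_abnormal: int = 241
    mean_abnormal: float = 35.5
    sd_abnormal: float = 14.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal < 1 or self.n_abnormal < 1:
            raise ValueError("group sizes must be positive")
        if self.sd_normal < 0 or self.sd_abnormal < 0:
            raise ValueError("standard deviations must be non-negative")


def sample_svef_population(spec: SvefPopulationSpec) -> "LabeledScores":
    """Draw a labelled SVEF score population from the two-Gaussian model.

    Scores are truncated to the physiologic [0, 100] % range; abnormal
    segments are the positive class.  Reproducible for a given seed.
    """
    from .roc import LabeledScores  # local import: roc does not depend on phantom

    rng = np.random.default_rng(spec.seed)
    normal = rng.normal(spec.mean_normal, spec.sd_normal, spec.n_normal)
    abnormal = rng.normal(spec.mean_abnormal, spec.sd_abnormal, spec.n_abnormal)
    scores = np.clip(np.concatenate([normal, abnormal]), 0.0, 100.0)
    labels = np.concatenate([np.zeros(spec.n_normal, int), np.ones(spec.n_abnormal, int)])
    return LabeledScores(scores=scores, labels=labels, model="model1")
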