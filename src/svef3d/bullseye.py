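"""Two-color bull's-eye maps and culprit-artery prediction.

A segment is tagged abnormal when its SVEF falls below the cutoff (default
44%); SVEF equal to or above the cutoff is normal — the same >= / < split
the ROC module optimises.  The abnormal pattern is then matched against the
three coronary territory templates by Jaccard similarity

    score(artery) = |abnormal ∩ template| / |abnormal ∪ template|

and the argmax is the predicted culprit.  Jaccard penalises both missed and
extra-territory segments symmetrically; a coverage alternative
(|∩| / |abnormal|) is available.  Ties, or an empty abnormal set, yield an
indeterminate prediction — real disagreement happens at the apex/septum, and
forcing a pick would hide it.

Rendering follows the standard display: basal ring outermost, apex at the
centre, anterior at the top, septum on the left, viewed from the apex.
Normal segments are drawn red, abnormal grey (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aha import SEGMENT_LABELS, TERRITORIES
from .svef import SvefTable

__all__ = ["BullseyeMap", "CulpritPrediction", "tag_segments", "predict_culprit", "render_bullseye"]

DEFAULT_CUTOFF = 44.0


@dataclass(frozen=True)
class BullseyeMap:
    """17 binary abnormal/normal tags plus the cutoff that produced them."""

    tags: dict[int, bool]  # True = abnormal
    cutoff_used: float

    def __post_init__(self) -> None:
        if set(self.tags) != set(SEGMENT_LABELS):
            raise ValueError("tags must cover exactly the 17 AHA segments")
        if self.cutoff_used <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def abnormal(self) -> frozenset[int]:
        return frozenset(s for s, bad in self.tags.items() if bad)


@dataclass(frozen=True)
class CulpritPrediction:
    artery: str  # "LAD" | "LCX" | "RCA" | "indeterminate"
    scores: dict[str, float]
    rule_trace: str

    def to_dict(self) -> dict:
        return {"artery": self.artery, "scores": dict(self.scores), "rule_trace": self.rule_trace}


def tag_segments(table: SvefTable, cutoff: float = DEFAULT_CUTOFF) -> BullseyeMap:
    """Tag each segment abnormal iff its SVEF is strictly below *cutoff*."""
    return BullseyeMap(tags={s: table.svef[s] < cutoff for s in SEGMENT_LABELS}, cutoff_used=cutoff)


def predict_culprit(
    bmap: BullseyeMap,
    templates: dict[str, frozenset[int]] | None = None,
    rule: str = "jaccard",
) -> CulpritPrediction:
    """Match the abnormal pattern against territory templates.

    ``rule``: ``"jaccard"`` (default) or ``"coverage"`` (|∩|/|abnormal|).
    Returns ``indeterminate`` for an empty abnormal set or a tied argmax.
    """
    tpl = TERRITORIES if templates is None else templates
    abnormal = bmap.abnormal
    if not abnormal:
        return CulpritPrediction("indeterminate", {a: 0.0 for a in tpl}, "no abnormal segments")

    scores, traces = {}, []
    for artery, segs in tpl.items():
        inter = abnormal & segs
        if rule == "jaccard":
            scores[artery] = len(inter) / len(abnormal | segs)
        elif rule == "coverage":
            scores[artery] = len(inter) / len(abnormal)
        else:
            raise ValueError(f"unknown rule {rule!r}")
        extra = sorted(abnormal - segs)
        traces.append(f"{artery}: matched {sorted(inter)}, outside territory {extra}")
    best = max(scores.values())
    winners = [a for a, s in scores.items() if s == best]
    artery = winners[0] if len(winners) == 1 else "indeterminate"
    return CulpritPrediction(artery, scores, "; ".join(traces))


# ---------------------------------------------------------------------------
# rendering

# (ring, sector span) layout: ring 0 = apex cap ... ring 3 = basal (outermost).
# Display angles are standard matplotlib polar degrees (0 = east, CCW);
# anterior at top (90), septum on the left half.
_RING_SEGMENTS = {
    3: [(1, 60, 120), (2, 120, 180), (3, 180, 240), (4, 240, 300), (5, 300, 360), (6, 0, 60)],
    2: [(7, 60, 120), (8, 120, 180), (9, 180, 240), (10, 240, 300), (11, 300, 360), (12, 0, 60)],
    1: [(13, 45, 135), (14, 135, 225), (15, 225, 315), (16, 315, 405)],
}
_RING_RADII = {1: (1.0, 2.0), 2: (2.0, 3.0), 3: (3.0, 4.0)}


def render_bullseye(
    bmap: BullseyeMap,
    path=None,
    normal_color: str = "#d62728",
    abnormal_color: str = "#9c9c9c",
    title: str | None = None,
):
    """Draw the two-color 17-segment polar plot; optionally save to *path*.

    Output is deterministic: rendering the same map twice produces identical
    SVG bytes (the SVG hash salt is pinned and no timestamp is embedded).
    Returns the matplotlib Figure.
    """
    import matplotlib

    matplotlib.rcParams["svg.hashsalt"] = "svef3d"
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle, Wedge

    fig, ax = plt.subplots(figsize=(5, 5), subplot_kw={"aspect": "equal"})
    ax.set_xlim(-4.4, 4.4)
    ax.set_ylim(-4.4, 4.4)
    ax.axis("off")

    def color(sid: int) -> str:
        return abnormal_color if bmap.tags[sid] else normal_color

    ax.add_patch(Circle((0, 0), 1.0, facecolor=color(17), edgecolor="black", lw=1.0))
    ax.annotate("17", (0, 0), ha="center", va="center", fontsize=9)
    for ring, segs in _RING_SEGMENTS.items():
        r_in, r_out = _RING_RADII[ring]
        for sid, a0, a1 in segs:
            ax.add_patch(
                Wedge((0, 0), r_out, a0, a1, width=r_out - r_in,
                      facecolor=color(sid), edgecolor="black", lw=1.0)
            )
            mid = np.radians((a0 + a1) / 2.0)
            r_mid = (r_in + r_out) / 2.0
            ax.annotate(str(sid), (r_mid * np.cos(mid), r_mid * np.sin(mid)),
                        ha="center", va="center", fontsize=9)
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, format=str(path).rsplit(".", 1)[-1].lower(),
                    metadata=({"Date": None} if str(path).lower().endswith(".svg") else None))
        plt.close(fig)
    return fig
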