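"""ROC analysis for the SVEF abnormality cutoff.

Two scoring models are supported: model 1 uses the raw segmental ejection
fraction (one universal cutoff in %), model 2 the ratio of each SVEF to the
subject's own global EF (unitless), intended to adapt the threshold to
globally depressed ventricles.  In both, *lower* scores indicate abnormal
wall motion, and abnormal is the positive class.

The AUC is the Mann-Whitney two-sample statistic P(abnormal score < normal
score), with ties counted 1/2 (midranks).  The operating cutoff c maximises
Youden's J = sensitivity + specificity - 1 over midpoints between adjacent
distinct scores, where

    sensitivity = P(score <  c | abnormal)
    specificity = P(score >= c | normal)

— the same >= / < split used to tag bull's-eye segments.  The AUC confidence
interval uses the Hanley-McNeil standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["LabeledScores", "RocResult", "roc_analysis", "model2_scores", "stratified_cutoffs"]


@dataclass(frozen=True)
class LabeledScores:
    """Scores with binary labels (1 = abnormal = positive class)."""

    scores: np.ndarray
    labels: np.ndarray
    model: str = "model1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, float))
        object.__setattr__(self, "labels", np.asarray(self.labels, int))
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be 1-D and the same length")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0 normal, 1 abnormal)")

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self.labels) - self.labels.sum())


@dataclass(frozen=True)
class RocResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    curve: np.ndarray = field(repr=False)  # (k, 2) of (FPR, TPR)
    ci_auc: tuple[float, float] = (np.nan, np.nan)
    youden_j: float = np.nan

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ci_auc": list(self.ci_auc),
            "youden_j": self.youden_j,
        }


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    # P(abnormal < normal) with midrank tie handling: rank ascending and use
    # the rank-sum of the *normal* group.
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = rankdata(scores)
    r_neg = ranks[labels == 0].sum()
    return (r_neg - n_neg * (n_neg + 1) / 2.0) / (n_pos * n_neg)


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_analysis(data: LabeledScores, criterion: str = "youden") -> RocResult:
    """Full ROC analysis of a labelled score set (lower score = abnormal).

    ``criterion`` selects the operating point: ``"youden"`` (default)
    maximises J; ``"closest"`` minimises the distance to the ideal corner
    (FPR 0, TPR 1).  Ties in the criterion resolve toward the cutoff with
    higher specificity.
    """
    if data.n_positive == 0 or data.n_negative == 0:
        raise ValueError("both classes must be present for ROC analysis")
    scores, labels = data.scores, data.labels
    auc = _auc_mann_whitney(scores, labels)
    se = _hanley_mcneil_se(auc, data.n_positive, data.n_negative)
    z = norm.ppf(0.975)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))

    # candidate cutoffs: midpoints between adjacent distinct scores, plus
    # sentinels below and above everything
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])

    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    sens = np.searchsorted(pos, candidates, side="left") / len(pos)   # P(pos < c)
    spec = 1.0 - np.searchsorted(neg, candidates, side="left") / len(neg)  # P(neg >= c)

    if criterion == "youden":
        objective = sens + spec - 1.0
    elif criterion == "closest":
        objective = -np.hypot(1.0 - spec, 1.0 - sens)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    best = np.flatnonzero(objective == objective.max())
    k = best[np.argmax(spec[best])]

    order = np.argsort(1.0 - spec, kind="stable")
    fpr = np.concatenate([[0.0], (1.0 - spec)[order], [1.0]])
    tpr = np.concatenate([[0.0], sens[order], [1.0]])
    curve = np.column_stack([fpr, tpr])

    return RocResult(
        auc=float(auc),
        cutoff=float(candidates[k]),
        sensitivity=float(sens[k]),
        specificity=float(spec[k]),
        curve=curve,
        ci_auc=ci,
        youden_j=float(sens[k] + spec[k] - 1.0),
    )


def model2_scores(tables, labels_by_subject: dict[str, dict[int, int]]) -> LabeledScores:
    """Normalise each subject's SVEFs by their own global EF (model 2).

    ``labels_by_subject`` maps subject_id -> {segment_id: 0/1 abnormal flag}
    (the reference wall-motion reading).  Returns one pooled score list with
    score = SVEF / global EF per segment.
    """
    scores, labels = [], []
    for t in tables:
        if t.global_ef <= 0:
            raise ValueError(f"subject {t.subject_id!r} has non-positive global EF")
        ref = labels_by_subject[t.subject_id]
        for sid, v in t.svef.items():
            scores.append(v / t.global_ef)
            labels.append(int(ref[sid]))
    return LabeledScores(np.array(scores), np.array(labels), model="model2")


def stratified_cutoffs(
    data: LabeledScores, strata: np.ndarray, criterion: str = "youden"
) -> dict[object, RocResult]:
    """Independent ROC analysis per stratum (e.g. global EF < vs >= 40%).

    ``strata`` assigns each score a stratum key; every stratum must contain
    both classes.
    """
    strata = np.asarray(strata)
    if strata.shape != data.scores.shape:
        raise ValueError("strata must align with scores")
    out = {}
    for key in np.unique(strata):
        m = strata == key
        sub = LabeledScores(data.scores[m], data.labels[m], model=data.model)
        if sub.n_positive == 0 or sub.n_negative == 0:
            raise ValueError(f"stratum {key!r} lacks one of the classes")
        out[key] = roc_analysis(sub, criterion)
    return out
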