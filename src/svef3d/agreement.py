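"""Agreement and group-comparison statistics.

Covers the statistics used to validate a segmental wall-motion classifier
against a reference reading: Cohen's kappa with an asymptotic confidence
interval and percent agreement for categorical calls (e.g. culprit-artery
predictions by two methods), the intraclass correlation for continuous
inter-observer reliability, one-way ANOVA with Bonferroni-corrected pairwise
contrasts across wall-motion score groups, and two-group mean +/- SD
summaries with a Welch t test.

kappa's standard error uses the full Fleiss-Cohen-Everitt asymptotic
variance of the chance-corrected statistic, not the simple agreement-only
approximation.  The ICC default is ICC(2,1): two-way random effects,
absolute agreement, single measures — the conservative choice for two fixed
observers measuring the same quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "cohen_kappa",
    "icc",
    "oneway_anova_bonferroni",
    "group_summary",
    "KappaResult",
    "IccResult",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K cross-tabulation; rows = rater/method A, columns = B."""

    counts: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, np.int64)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if c.sum() < 1:
            raise ValueError("confusion matrix must contain at least one observation")
        if not self.labels:
            object.__setattr__(self, "labels", tuple(str(i) for i in range(c.shape[0])))
        elif len(self.labels) != c.shape[0]:
            raise ValueError("one label per category required")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_pairs(cls, a, b, labels=None) -> "ConfusionMatrix":
        labels = sorted(set(a) | set(b)) if labels is None else list(labels)
        idx = {lab: i for i, lab in enumerate(labels)}
        c = np.zeros((len(labels), len(labels)), np.int64)
        for x, y in zip(a, b):
            c[idx[x], idx[y]] += 1
        return cls(c, tuple(str(l) for l in labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    percent_agreement: float
    se: float
    ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "percent_agreement": self.percent_agreement,
            "se": self.se,
            "ci": list(self.ci),
        }


def cohen_kappa(m: ConfusionMatrix) -> KappaResult:
    """Cohen's kappa, percent agreement and a 95% asymptotic CI.

    kappa = (Po - Pe) / (1 - Pe) with Po the diagonal fraction and Pe the
    chance agreement from the marginals.  Po and Pe are carried as exact
    rationals up to the final division.  The CI is kappa +/- 1.96 SE with
    the Fleiss-Cohen-Everitt large-sample variance.
    """
    c = m.counts
    n = m.n
    po_f = Fraction(int(np.trace(c)), n)
    pe_f = Fraction(int((c.sum(axis=1) * c.sum(axis=0)).sum()), n * n)
    if pe_f == 1:
        raise ValueError("degenerate table: chance agreement is 1 (single category)")
    kappa = float(Fraction(po_f - pe_f, 1 - pe_f))

    p = c / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(po_f)
    pe = float(pe_f)
    diag = np.diag(p)
    term1 = (diag * ((1 - pe) - (row + col) * (1 - po)) ** 2).sum()
    off = p * (col[:, None] + row[None, :]) ** 2
    np.fill_diagonal(off, 0.0)
    term2 = (1 - po) ** 2 * off.sum()
    term3 = (po * pe - 2 * pe + po) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    return KappaResult(
        kappa=kappa,
        percent_agreement=100.0 * po,
        se=se,
        ci=(kappa - 1.959963984540054 * se, kappa + 1.959963984540054 * se),
    )


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci: tuple[float, float]
    form: str
    ms: dict[str, float]

    def to_dict(self) -> dict:
        return {"icc": self.icc, "ci": list(self.ci), "form": self.form, "ms": dict(self.ms)}


def icc(ratings: np.ndarray, form: str = "ICC(2,1)", alpha: float = 0.05) -> IccResult:
    """Intraclass correlation from an items x raters matrix.

    Forms: ``ICC(2,1)`` (default; two-way random, absolute agreement, single
    measures), ``ICC(3,1)`` (two-way mixed, consistency) and ``ICC(1,1)``
    (one-way random).  Rows containing NaN are dropped listwise.  The CI is
    the standard F-based interval.  Raises if the between-item variance is
    zero (reliability undefined).
    """
    x = np.asarray(ratings, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an (items >= 2) x (raters >= 2) matrix")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 2:
        raise ValueError("fewer than 2 complete items after listwise deletion")

    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = (ss_total - ss_rows) / (n * (k - 1))
    ms = {"MSR": msr, "MSC": msc, "MSE": mse, "MSW": msw}

    if msr <= 1e-300:
        raise ValueError("zero between-item variance: ICC undefined")

    if form == "ICC(2,1)":
        val = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        # Shrout-Fleiss F-based interval with Satterthwaite df
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (k * val * fj + n * (1 + (k - 1) * val) - k * val) ** 2
        vd = (n - 1) * k**2 * val**2 * fj**2 + (n * (1 + (k - 1) * val) - k * val) ** 2
        v = vn / vd
        f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    elif form == "ICC(3,1)":
        val = (msr - mse) / (msr + (k - 1) * mse)
        fobs = msr / mse
        f_l = fobs / stats.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        f_u = fobs * stats.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        lo = (f_l - 1) / (f_l + k - 1)
        hi = (f_u - 1) / (f_u + k - 1)
    elif form == "ICC(1,1)":
        val = (msr - msw) / (msr + (k - 1) * msw)
        fobs = msr / msw
        f_l = fobs / stats.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
        f_u = fobs * stats.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
        lo = (f_l - 1) / (f_l + k - 1)
        hi = (f_u - 1) / (f_u + k - 1)
    else:
        raise ValueError(f"unsupported ICC form {form!r}")
    return IccResult(icc=float(val), ci=(float(lo), float(hi)), form=form, ms=ms)


def oneway_anova_bonferroni(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA across labelled groups plus Bonferroni pairwise t tests.

    Pairwise contrasts are ordinary two-sample (pooled-variance) t tests with
    p multiplied by the number of comparisons and capped at 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:  # identical constants: no variance anywhere
        f, p = 0.0, 1.0
    else:
        f, p = stats.f_oneway(*arrays.values())

    names = list(arrays)
    m = len(names) * (len(names) - 1) // 2
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if np.ptp(np.concatenate([arrays[a], arrays[b]])) == 0:
                t, praw = 0.0, 1.0
            else:
                t, praw = stats.ttest_ind(arrays[a], arrays[b])
            pairwise[(a, b)] = {"t": float(t), "p_raw": float(praw), "p_adj": float(min(1.0, praw * m))}
    return {"F": float(f), "p": float(p), "pairwise": pairwise}


def group_summary(values: np.ndarray, is_abnormal: np.ndarray) -> dict:
    """Mean +/- SD per binary class and the Welch two-sample p value.

    SD uses the n-1 denominator.  Both classes must have n >= 2.
    """
    values = np.asarray(values, float)
    is_abnormal = np.asarray(is_abnormal, bool)
    a = values[~is_abnormal]
    b = values[is_abnormal]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs n >= 2 for an SD and a t test")
    if a.std() == 0 and b.std() == 0:  # degenerate: both classes constant
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        _, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "normal": {"n": len(a), "mean": float(a.mean()), "sd": float(a.std(ddof=1))},
        "abnormal": {"n": len(b), "mean": float(b.mean()), "sd": float(b.std(ddof=1))},
        "p": float(p),
    }
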