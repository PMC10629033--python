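"""Alignment quality metrics and the accompanying statistical tests.

Node correctness (NC) is the fraction of aligned pairs that match the
known true mapping; the *alignment score* is NC after unity-based
(min–max) feature scaling over a benchmark run.  Confusion counts treat a
correctly mapped pair as a true positive, a contradicted pair as a false
positive and a missed truth pair as a false negative; under a forced
one-to-one alignment of all source nodes there are no predicted negatives
at the pair level, so TN = 0 at that operating point (thresholded ROC
analysis is where true negatives become meaningful).  Statistical support
is one-way ANOVA over noise groups — computable both from raw scores and
from printed per-group summaries (n, mean, SD) — and McNemar's test with
continuity correction on the discordant cells of a 2x2 contingency table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .alignment import Alignment
from .synthetic import TrueMapping

__all__ = [
    "ConfusionCounts",
    "GroupSummary",
    "AnovaResult",
    "EvaluationReport",
    "node_correctness",
    "alignment_score",
    "confusion_counts",
    "roc_auc",
    "f1_score",
    "f1_scores",
    "mcc",
    "anova_from_summary",
    "anova_from_raw",
    "mcnemar",
    "descriptive",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0


@dataclass(frozen=True)
class GroupSummary:
    """Per-group descriptive statistics (one noise level = one group)."""

    label: str
    n: int
    mean: float
    sd: float
    se: float
    cv: float


@dataclass(frozen=True)
class AnovaResult:
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    F: float
    p: float


@dataclass
class EvaluationReport:
    """All KPIs of one alignment against its true mapping."""

    nc: float
    counts: ConfusionCounts
    tpr: float
    fpr: float
    auc: float
    f1: float
    mcc: float
    alignment_score: float | None = None
    roc_curve: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "nc": self.nc,
            "alignment_score": self.alignment_score,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
            "precision": self.counts.precision,
            "recall": self.counts.recall,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "auc": self.auc,
            "f1": self.f1,
            "mcc": self.mcc,
        }


# ---------------------------------------------------------------------------
# KPI primitives


def node_correctness(a: Alignment, t: TrueMapping) -> float:
    """Ratio of aligned node pairs that agree with the true mapping."""
    if len(t) == 0:
        raise ValueError("true mapping is empty")
    correct = sum(1 for v, u, _ in a.pairs if v in t and t[v] == u)
    return correct / len(t)


def alignment_score(nc_values: Sequence[float]) -> list[float]:
    """Unity-based (min–max) feature scaling of NC values over a run.

    When every value is identical there is no scale to normalise over;
    the raw values are returned unchanged.
    """
    vals = list(nc_values)
    if not vals:
        raise ValueError("empty NC list")
    lo, hi = min(vals), max(vals)
    if hi == lo:
        return vals
    return [(x - lo) / (hi - lo) for x in vals]


def confusion_counts(a: Alignment, t: TrueMapping) -> ConfusionCounts:
    """Pair-level confusion counts at the all-pairs operating point (TN = 0)."""
    mapping = a.mapping
    tp = sum(1 for v, u in t.items() if mapping.get(v) == u)
    fp = sum(1 for v, u, _ in a.pairs if not (v in t and t[v] == u))
    fn = len(t) - tp
    return ConfusionCounts(tp=tp, fp=fp, tn=0, fn=fn)


def roc_auc(
    a: Alignment, t: TrueMapping
) -> tuple[list[tuple[float, float]], float]:
    """ROC curve and AUC from a threshold sweep over per-pair scores.

    Pairs scoring at or above each threshold (descending unique scores)
    are classified as predicted matches; TPR/FPR are computed against the
    truth labels of the aligned pairs.  AUC is the trapezoid area; the
    curve is anchored at (0,0) and (1,1).  Degenerate cases: all-equal
    scores give the two anchor points and AUC 0.5; a single-class label
    set has no sweep and returns AUC 1.0 (all correct) or 0.0 (none).
    """
    scores = np.array([s for _, _, s in a.pairs], dtype=float)
    labels = np.array([1 if (v in t and t[v] == u) else 0 for v, u, _ in a.pairs])
    P = int(labels.sum())
    N = len(labels) - P
    if P == 0 or N == 0:
        anchor = [(0.0, 0.0), (1.0, 1.0)]
        return anchor, (1.0 if N == 0 else 0.0)
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            tp += int(labels[j])
            fp += 1 - int(labels[j])
            j += 1
        points.append((fp / N, tp / P))
        i = j
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    xs = np.array([x for x, _ in points])
    ys = np.array([y for _, y in points])
    auc = float(np.trapezoid(ys, xs))
    return points, auc


def f1_score(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    p, r = c.precision, c.recall
    return 2 * p * r / (p + r) if (p + r) else 0.0


def f1_scores(
    per_alignment_counts: Sequence[ConfusionCounts],
    noise_labels: Sequence,
) -> tuple[float, float, float]:
    """Aggregate F1 over a benchmark: average, maximum and normalised.

    The normalised variant min–max scales the per-alignment F1 values
    within each noise level (the grouping the normalisation is calculated
    on) and averages the scaled values.
    """
    if not per_alignment_counts:
        raise ValueError("no confusion counts supplied")
    if len(per_alignment_counts) != len(noise_labels):
        raise ValueError("counts and noise labels differ in length")
    f1s = np.array([f1_score(c) for c in per_alignment_counts])
    by_level: dict = {}
    for f1v, lab in zip(f1s, noise_labels):
        by_level.setdefault(lab, []).append(f1v)
    scaled: list[float] = []
    for lab, vals in by_level.items():
        scaled.extend(alignment_score(vals))
    return float(f1s.mean()), float(f1s.max()), float(np.mean(scaled))


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / denom


# ---------------------------------------------------------------------------
# statistics


def anova_from_summary(groups: Sequence[GroupSummary]) -> AnovaResult:
    """One-way ANOVA from per-group (n, mean, SD) summaries.

    ``SS_between = Σ n_i (mean_i - grand_mean)^2`` with the grand mean
    weighted by group size; ``SS_within = Σ (n_i - 1) sd_i^2`` (sample SDs,
    n-1 denominator).  The p-value is the upper tail of the F
    distribution with (k-1, Σn_i - k) degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(g.n < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    grand = float((ns * means).sum() / ns.sum())
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_between = len(groups) - 1
    df_within = int(ns.sum()) - len(groups)
    ms_between = ss_between / df_between
    if ss_within == 0.0:
        if ss_between > 0.0:
            return AnovaResult(
                ss_between, 0.0, df_between, df_within, ms_between, 0.0,
                float("inf"), 0.0,
            )
        return AnovaResult(
            0.0, 0.0, df_between, df_within, 0.0, 0.0, 0.0, 1.0
        )
    ms_within = ss_within / df_within
    F = ms_between / ms_within
    p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(
        ss_between, ss_within, df_between, df_within, ms_between, ms_within, F, p
    )


def anova_from_raw(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA from raw per-group observations."""
    return anova_from_summary(descriptive(groups))


def mcnemar(b: int, c: int, exact: bool = False) -> tuple[float, float]:
    """McNemar's test on the discordant counts of a 2x2 contingency table.

    Default: continuity-corrected chi-square,
    ``chi2 = (max(|b - c| - 1, 0))^2 / (b + c)``, with the two-tailed
    p-value from the upper tail of chi-square with 1 degree of freedom
    (the corrected statistic is inherently two-sided).  With
    ``exact=True`` the exact two-sided binomial p-value is returned
    instead (the statistic is then ``min(b, c)``).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        raise ValueError("McNemar's test is undefined when b + c = 0")
    if exact:
        p = float(stats.binomtest(min(b, c), b + c, 0.5).pvalue)
        return float(min(b, c)), p
    chi2 = max(abs(b - c) - 1, 0) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def descriptive(groups: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """Sample mean, SD (n-1), SE and coefficient of variation per group."""
    out: list[GroupSummary] = []
    for label, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        n = arr.size
        if n == 0:
            raise ValueError(f"group {label!r} is empty")
        if n == 1:
            raise ValueError(f"group {label!r} has n=1; SD is undefined")
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1))
        se = sd / math.sqrt(n)
        cv = sd / mean if mean != 0 else float("nan")
        out.append(GroupSummary(str(label), n, mean, sd, se, cv))
    return out


# ---------------------------------------------------------------------------
# report


def evaluate(a: Alignment, t: TrueMapping) -> EvaluationReport:
    """Full KPI report for one alignment against its true mapping.

    TPR and FPR are reported at the all-pairs operating point (every
    aligned pair counts as a predicted match, TN = 0); the ROC curve and
    AUC come from the threshold sweep over per-pair similarity scores.
    """
    counts = confusion_counts(a, t)
    curve, auc = roc_auc(a, t)
    tpr = counts.recall
    fpr = counts.fp / (counts.fp + counts.tn) if (counts.fp + counts.tn) else 0.0
    return EvaluationReport(
        nc=node_correctness(a, t),
        counts=counts,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        f1=f1_score(counts),
        mcc=mcc(counts),
        roc_curve=curve,
    )
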