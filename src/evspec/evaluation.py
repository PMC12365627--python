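"""Diagnostic performance metrics and group statistics.

Covers the confusion-matrix metrics (sensitivity, specificity, PPV, NPV,
accuracy), the Wilcoxon rank-sum / Mann-Whitney U test (exact enumeration
for small samples, normal approximation with continuity correction
otherwise), ROC curves with trapezoid AUC and a Hanley-McNeil 95 % CI, box
plot summaries, and a per-band group-intensity report with
Benjamini-Hochberg multiple-testing control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import rankdata

from .core import EvspecError, LabeledDataset

EXACT_ENUMERATION_LIMIT = 10  # exact U-test null up to this pooled size


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise EvspecError("confusion counts must be nonnegative")
        if self.TP + self.TN + self.FP + self.FN == 0:
            raise EvspecError("confusion matrix total must be positive")


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV, NPV and accuracy as fractions.

    A metric whose denominator is zero is returned as None (undefined)
    rather than raising.
    """
    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    total = cm.TP + cm.TN + cm.FP + cm.FN
    return {
        "sensitivity": ratio(cm.TP, cm.TP + cm.FN),
        "specificity": ratio(cm.TN, cm.TN + cm.FP),
        "ppv": ratio(cm.TP, cm.TP + cm.FP),
        "npv": ratio(cm.TN, cm.TN + cm.FN),
        "accuracy": (cm.TP + cm.TN) / total,
    }


@dataclass(frozen=True)
class RankTestResult:
    U: float
    p: float
    n1: int
    n2: int
    method: str


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for the first sample via midranks."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = ranks[: a.size].sum()
    return float(r1 - a.size * (a.size + 1) / 2.0)


def mann_whitney_u(a, b) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney U test.

    Exact p by enumerating all rank splits when n1 + n2 <= 10 (valid under
    ties because the pooled values are permuted, not the ranks); otherwise
    the normal approximation with tie-corrected variance and a continuity
    correction.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise EvspecError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    U = _u_statistic(a, b)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= EXACT_ENUMERATION_LIMIT:
        pooled = np.concatenate([a, b])
        dev = abs(U - mu)
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            total += 1
            u = _u_statistic(pooled[list(idx)], np.delete(pooled, list(idx)))
            if abs(u - mu) >= dev - 1e-12:
                count += 1
        return RankTestResult(U, count / total, n1, n2, "exact")

    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return RankTestResult(U, 1.0, n1, n2, "normal")
    z = (abs(U - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, math.erfc(max(z, 0.0) / math.sqrt(2.0)))
    return RankTestResult(U, p, n1, n2, "normal")


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    ci95: tuple[float, float]


def _hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)) / (
        n_pos * n_neg
    )
    se = math.sqrt(max(var, 0.0))
    return (auc - 1.96 * se, auc + 1.96 * se)


def roc_curve(scores, labels, positive=1) -> ROCResult:
    """ROC by threshold sweep over the unique scores; trapezoid AUC.

    ``labels`` are compared against ``positive``.  The curve is anchored at
    (0, 0) and (1, 1); the 95 % CI uses the Hanley-McNeil normal
    approximation.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvspecError("ROC requires both classes present")

    thr = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = np.empty(thr.size)
    fpr = np.empty(thr.size)
    for i, t in enumerate(thr):
        call_pos = scores >= t
        tpr[i] = np.sum(call_pos & pos) / n_pos
        fpr[i] = np.sum(call_pos & ~pos) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thr, tpr, fpr, auc, _hanley_mcneil_ci(auc, n_pos, n_neg))


def auc_from_ranks(scores, labels, positive=1) -> float:
    """AUC via the rank identity U / (n1 n2); equals trapezoid AUC.

    With midranks this also handles ties (each tie contributes 1/2).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    pos = labels == positive
    U = _u_statistic(scores[pos], scores[~pos])
    return float(U / (pos.sum() * (~pos).sum()))


@dataclass(frozen=True)
class BoxStats:
    min: float
    q1: float
    median: float
    q3: float
    max: float
    whisker_low: float
    whisker_high: float
    mean: float


def box_stats(values) -> BoxStats:
    """Five-number summary with linear-interpolation quartiles.

    Whiskers span the full data range (minima/maxima convention).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise EvspecError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return BoxStats(float(v.min()), float(q1), float(med), float(q3),
                    float(v.max()), float(v.min()), float(v.max()), float(v.mean()))


def band_intensity(y: np.ndarray, axis, center: float, half_width: float = 4.0) -> float:
    """Mean intensity in a +-half_width cm^-1 window around a band center."""
    wn = axis.values
    if not axis.contains(center):
        raise EvspecError(f"band {center} outside axis")
    mask = np.abs(wn - center) <= half_width
    return float(np.mean(np.asarray(y)[mask]))


def band_intensity_report(
    dataset: LabeledDataset,
    bands,
    group_by: str = "state",
    groups: tuple[str, str] = ("healthy", "cvd"),
    half_width: float = 4.0,
    fdr: bool = True,
    alpha: float = 0.05,
) -> list[dict]:
    """Per-band group comparison: means, box stats, Mann-Whitney p.

    With ``fdr`` (default) p-values are Benjamini-Hochberg adjusted across
    bands at level ``alpha``; raw per-band p-values are always reported.
    """
    g1, g2 = groups
    rows = []
    for center in bands:
        vals = {g1: [], g2: []}
        for s in dataset.spectra:
            key = getattr(s, group_by)
            if key in vals:
                vals[key].append(band_intensity(s.intensities, dataset.axis, center, half_width))
        x1, x2 = np.array(vals[g1]), np.array(vals[g2])
        if x1.size == 0 or x2.size == 0:
            raise EvspecError(f"a group is empty for band {center}")
        test = mann_whitney_u(x1, x2)
        rows.append({
            "band": float(center),
            f"mean_{g1}": float(x1.mean()),
            f"mean_{g2}": float(x2.mean()),
            f"box_{g1}": box_stats(x1),
            f"box_{g2}": box_stats(x2),
            "U": test.U,
            "p": test.p,
        })
    if fdr:
        from statsmodels.stats.multitest import multipletests
        reject, p_adj, _, _ = multipletests([r["p"] for r in rows], alpha=alpha, method="fdr_bh")
        for r, pa, rej in zip(rows, p_adj, reject):
            r["p_adjusted"] = float(pa)
            r["significant"] = bool(rej)
    else:
        for r in rows:
            r["significant"] = r["p"] < alpha
    return rows
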