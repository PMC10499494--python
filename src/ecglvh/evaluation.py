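"""Scoring criteria against reference LVH labels.

Confusion metrics, the McNemar discordant-pair test, MMCV-based ROC/AUROC
(AUROC equals the Mann–Whitney statistic with ties credited one half) and
the Pearson correlation of the criterion statistic with LVMI.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

#: Below this many discordant pairs the exact binomial McNemar p is used.
MCNEMAR_EXACT_BELOW = 25


@dataclass
class EvalReport:
    """Aggregate performance of one criterion against the reference label."""

    n: int = 0
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    accuracy: float = math.nan
    sensitivity: float = math.nan
    specificity: float = math.nan
    ppv: float = math.nan
    npv: float = math.nan
    odds_ratio: float = math.nan
    odds_ratio_corrected: bool = False
    mcnemar_chi2: float = math.nan
    mcnemar_p: float = math.nan
    mcnemar_exact: bool = False
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    roc_thresholds: list[float] = field(default_factory=list)
    auroc: float = math.nan
    pearson_r: float = math.nan

    def to_dict(self) -> dict:
        out = {}
        for key, value in self.__dict__.items():
            if isinstance(value, float):
                out[key] = None if math.isnan(value) else (
                    "inf" if math.isinf(value) else value)
            elif key == "roc_points":
                out[key] = [[float(f), float(t)] for f, t in value]
            elif key == "roc_thresholds":
                out[key] = [None if math.isinf(v) else float(v) for v in value]
            else:
                out[key] = value
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _as_bool(vec) -> np.ndarray:
    return np.asarray(vec, dtype=bool)


def confusion_metrics(calls, labels) -> EvalReport:
    """Counts, rates, and the odds ratio (Haldane–Anscombe 0.5 correction
    applied, and flagged, when any cell is zero)."""
    calls, labels = _as_bool(calls), _as_bool(labels)
    if calls.shape != labels.shape or calls.ndim != 1 or calls.size == 0:
        raise ValueError("calls and labels must be equal-length non-empty vectors")
    tp = int(np.sum(calls & labels))
    fp = int(np.sum(calls & ~labels))
    tn = int(np.sum(~calls & ~labels))
    fn = int(np.sum(~calls & labels))
    n = calls.size
    rep = EvalReport(n=n, tp=tp, fp=fp, tn=tn, fn=fn)
    rep.accuracy = (tp + tn) / n
    rep.sensitivity = tp / (tp + fn) if tp + fn else math.nan
    rep.specificity = tn / (tn + fp) if tn + fp else math.nan
    rep.ppv = tp / (tp + fp) if tp + fp else math.nan
    rep.npv = tn / (tn + fn) if tn + fn else math.nan
    if min(tp, fp, tn, fn) == 0:
        rep.odds_ratio_corrected = True
        a, b, c, d = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
        rep.odds_ratio = (a * d) / (b * c)
    else:
        rep.odds_ratio = (tp * tn) / (fp * fn)
    return rep


def mcnemar(calls, labels) -> tuple[float, float, bool]:
    """McNemar test on the discordant pairs.

    chi2 = (b - c)^2 / (b + c) without continuity correction, with b the
    call-positive/label-negative and c the call-negative/label-positive
    counts; p from chi-square(1). When b + c < 25 the p-value switches to
    the exact two-sided binomial. Returns ``(chi2, p, used_exact)``;
    b + c = 0 yields (0, 1, True).
    """
    calls, labels = _as_bool(calls), _as_bool(labels)
    if calls.shape != labels.shape:
        raise ValueError("calls and labels must have equal length")
    b = int(np.sum(calls & ~labels))
    c = int(np.sum(~calls & labels))
    if b + c == 0:
        return 0.0, 1.0, True
    chi2 = (b - c) ** 2 / (b + c)
    if b + c < MCNEMAR_EXACT_BELOW:
        p = float(stats.binomtest(min(b, c), b + c, 0.5).pvalue)
        return float(chi2), min(p, 1.0), True
    return float(chi2), float(stats.chi2.sf(chi2, df=1)), False


def _auroc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC via the Mann–Whitney rank identity.

    Midranks make tied pairs contribute exactly one half, so the result
    agrees with brute-force pair counting to the last bit for tie-free
    input (rank sums are integer-valued in double precision).
    """
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = float(ranks[labels].sum()) - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


def roc_and_auroc(scores, labels) -> tuple[list[tuple[float, float]],
                                           list[float], float]:
    """ROC by descending-score threshold sweep plus the AUROC.

    Ties are grouped at one threshold step, so the AUROC equals the
    Mann–Whitney statistic P(score+ > score-) + 0.5 * P(tie). Returns
    (roc_points, thresholds, auroc); raises when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _as_bool(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    for cls, name in ((True, "positive"), (False, "negative")):
        if not np.any(labels == cls):
            raise ValueError(f"ROC undefined: no {name} labels present")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    auroc = _auroc_rank(scores, labels)
    points = list(zip(fpr.tolist(), tpr.tolist()))
    return points, thresholds.tolist(), auroc


def bootstrap_auroc_ci(scores, labels, n_resamples: int = 1000,
                       alpha: float = 0.05, seed: int = 0) -> tuple[float, float]:
    """Seeded percentile bootstrap CI for the AUROC."""
    scores = np.asarray(scores, dtype=float)
    labels = _as_bool(labels)
    rng = np.random.default_rng(seed)
    n = scores.size
    vals = []
    for _ in range(n_resamples):
        idx = rng.integers(0, n, n)
        if labels[idx].all() or not labels[idx].any():
            continue
        vals.append(_auroc_rank(scores[idx], labels[idx]))
    return (float(np.quantile(vals, alpha / 2)),
            float(np.quantile(vals, 1 - alpha / 2)))


def pearson(scores, reference) -> float:
    """Sample Pearson correlation; rejects constant or too-short inputs."""
    scores = np.asarray(scores, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if scores.shape != reference.shape or scores.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.ptp(scores) == 0 or np.ptp(reference) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(scores, reference)[0])


def evaluate_criterion(scores, calls, labels, lvmi=None) -> EvalReport:
    """Full report: confusion metrics, McNemar, ROC/AUROC and optionally
    the Pearson correlation of the score with LVMI."""
    rep = confusion_metrics(calls, labels)
    rep.mcnemar_chi2, rep.mcnemar_p, rep.mcnemar_exact = mcnemar(calls, labels)
    labels_arr = _as_bool(labels)
    if labels_arr.any() and not labels_arr.all():
        rep.roc_points, rep.roc_thresholds, rep.auroc = roc_and_auroc(scores, labels)
    if lvmi is not None:
        rep.pearson_r = pearson(scores, lvmi)
    return rep
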