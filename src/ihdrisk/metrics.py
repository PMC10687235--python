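"""Discrimination metrics and comparison statistics for risk models.

AUROC is the c-statistic (probability a random case outranks a random
control, ties counted one half); AUCPR is the non-interpolated area
under the precision-recall step curve, whose chance level equals outcome
prevalence.  Confidence intervals use the stratified bootstrap
(resampling cases and controls separately); AUROC comparisons use the
paired DeLong test and AUCPR comparisons a paired stratified bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score


def _validate(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("need both classes present")
    return scores, labels


def auroc(scores, labels) -> float:
    """Rank-based AUROC with ties counted one half (Mann-Whitney form)."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aucpr(scores, labels) -> float:
    """Average precision: the non-interpolated precision-recall step area."""
    scores, labels = _validate(scores, labels)
    return float(average_precision_score(labels, scores))


def stratified_bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI resampling cases and controls separately.

    Preserving prevalence in every replicate matters at low event rates.
    Deterministic per seed; ``n_boot`` below 10 is refused.
    """
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10 for a meaningful interval")
    scores, labels = _validate(scores, labels)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=pos.size), rng.choice(neg, size=neg.size)]
        )
        vals[b] = metric(scores[idx], labels[idx])
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUROC plus per-case and per-control structural components (V10, V01)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # Placement values via midranks (ties at 1/2)
    v10 = np.array([(s > neg).mean() + 0.5 * (s == neg).mean() for s in pos])
    v01 = np.array([(pos > s).mean() + 0.5 * (pos == s).mean() for s in neg])
    return float(v10.mean()), v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired DeLong comparison of two AUROCs on the same cases.

    Returns (AUROC_a - AUROC_b, two-tailed normal p).  Identical score
    vectors (degenerate zero variance) report Δ = 0 with p = 1.
    """
    scores_a, labels = _validate(scores_a, labels)
    scores_b, _ = _validate(scores_b, labels)
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = auc_a - auc_b
    if var <= 0:
        return float(delta), 1.0 if np.isclose(delta, 0.0) else 0.0
    z = delta / np.sqrt(var)
    return float(delta), float(2 * stats.norm.sf(abs(z)))


def bootstrap_compare_aucpr(
    scores_a, scores_b, labels, n_boot: int = 2000, seed: int = 0
) -> float:
    """Two-tailed p for an AUCPR difference via paired stratified bootstrap.

    Resamples indices once per replicate and evaluates both models on the
    same replicate, then inverts the percentile of 0 in the difference
    distribution.
    """
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10")
    scores_a, labels = _validate(scores_a, labels)
    scores_b, _ = _validate(scores_b, labels)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=pos.size), rng.choice(neg, size=neg.size)]
        )
        diffs[b] = aucpr(scores_a[idx], labels[idx]) - aucpr(scores_b[idx], labels[idx])
    if np.allclose(diffs, 0.0):
        return 1.0
    p_one = min((diffs <= 0).mean(), (diffs >= 0).mean())
    return float(min(1.0, 2 * p_one))


@dataclass(frozen=True)
class OperatingPoint:
    """Threshold with its confusion-derived rates; J = sens + spec - 1."""

    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden_j: float


def youden_operating_point(scores, labels) -> OperatingPoint:
    """Operating point at the threshold maximizing Youden's J.

    Predictions are ``score >= threshold``; candidate thresholds are the
    observed scores; ties in J resolve to the lowest threshold (maximal
    sensitivity at equal J).
    """
    scores, labels = _validate(scores, labels)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    thresholds = np.unique(scores)
    best = None
    for thr in thresholds:  # ascending, so first strict improvement keeps lowest
        pred = scores >= thr
        tp = int((pred & (labels == 1)).sum())
        tn = int((~pred & (labels == 0)).sum())
        fp = int((pred & (labels == 0)).sum())
        fn = int((~pred & (labels == 1)).sum())
        sens = tp / n_pos
        spec = tn / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec, tp, tn, fp, fn)
    j, thr, sens, spec, tp, tn, fp, fn = best
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return OperatingPoint(float(thr), sens, spec, ppv, npv, j)


@dataclass(frozen=True)
class EvalResult:
    """Point metrics with stratified-bootstrap 95% CIs."""

    auroc: float
    auroc_ci: tuple[float, float]
    aucpr: float
    aucpr_ci: tuple[float, float]
    n: int
    n_boot: int
    seed: int


def evaluate_scores(scores, labels, n_boot: int = 2000, seed: int = 0) -> EvalResult:
    """AUROC and AUCPR with stratified-bootstrap confidence intervals."""
    scores, labels = _validate(scores, labels)
    return EvalResult(
        auroc=auroc(scores, labels),
        auroc_ci=stratified_bootstrap_ci(auroc, scores, labels, n_boot, seed),
        aucpr=aucpr(scores, labels),
        aucpr_ci=stratified_bootstrap_ci(aucpr, scores, labels, n_boot, seed + 1),
        n=labels.size,
        n_boot=n_boot,
        seed=seed,
    )


def subgroup_eval(
    scores,
    labels,
    groups,
    min_size: int = 20,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Per-subgroup evaluation table.

    Groups smaller than ``min_size`` (or single-class) are flagged with a
    reason instead of metrics — never silently dropped.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    groups = np.asarray(groups)
    out: dict = {}
    for g in np.unique(groups):
        sel = groups == g
        sub_labels = labels[sel]
        if sel.sum() < min_size:
            out[g] = {"flag": "too_small", "n": int(sel.sum())}
        elif len(np.unique(sub_labels)) < 2:
            out[g] = {"flag": "single_class", "n": int(sel.sum())}
        else:
            out[g] = evaluate_scores(scores[sel], sub_labels, n_boot=n_boot, seed=seed)
    return out
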