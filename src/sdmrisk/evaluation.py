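"""Accuracy metrics, MTSS threshold selection and replicate summaries.

The decision rule everywhere is "score >= threshold -> predicted presence",
so threshold 0 is the all-presence boundary. TSS = sensitivity +
specificity - 1 holds exactly before any report rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

METRIC_ROWS = ("threshold", "sensitivity", "specificity", "tss", "kappa",
               "accuracy", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvalResult:
    """One model x replicate evaluation row (threshold plus six metrics)."""

    threshold: float
    sensitivity: float
    specificity: float
    tss: float
    kappa: float
    accuracy: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_ROWS}


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if scores.size == 0:
        raise ValueError("empty input")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    return scores, labels.astype(int)


def confusion(scores, labels, threshold: float) -> ConfusionCounts:
    """Counts under the rule: predicted presence iff score >= threshold."""
    scores, labels = _check_scores_labels(scores, labels)
    pred = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        tn=int(np.sum(~pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, TSS, Cohen's kappa, overall accuracy.

    Undefined ratios (an absent class) are reported as NaN, never as 0.
    """
    n = c.total
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else math.nan
    acc = (c.tp + c.tn) / n
    p_yes = ((c.tp + c.fp) / n) * ((c.tp + c.fn) / n)
    p_no = ((c.tn + c.fn) / n) * ((c.tn + c.fp) / n)
    p_e = p_yes + p_no
    kappa = (acc - p_e) / (1 - p_e) if p_e < 1 else math.nan
    return {
        "sensitivity": sens,
        "specificity": spec,
        "tss": sens + spec - 1,
        "kappa": kappa,
        "accuracy": acc,
    }


def auc(scores, labels) -> float:
    """Rank-based AUC: P(random presence outscores random background), ties half."""
    scores, labels = _check_scores_labels(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes")
    return float(roc_auc_score(labels, scores))


def mtss_threshold(scores, labels) -> tuple[float, float]:
    """Threshold (from observed scores) maximizing sensitivity + specificity.

    Returns ``(threshold, best_tss)``; ties resolve to the smallest
    threshold. The best TSS may be <= 0 on anti-separated data.
    """
    scores, labels = _check_scores_labels(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold selection needs both classes")
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    candidates = np.unique(scores)
    best_t, best_tss = candidates[0], -np.inf
    for t in candidates:
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        tss = sens + spec - 1
        if tss > best_tss + 1e-12:
            best_t, best_tss = t, tss
    return float(best_t), float(best_tss)


def evaluate(train_scores, train_labels, test_scores, test_labels) -> EvalResult:
    """Full evaluation row: MTSS threshold on training, metrics on test."""
    t, _ = mtss_threshold(train_scores, train_labels)
    m = metrics(confusion(test_scores, test_labels, t))
    return EvalResult(threshold=t, auc=auc(test_scores, test_labels), **m)


def summarize_replicates(results: dict[str, list[EvalResult]]) -> pd.DataFrame:
    """Per-algorithm mean and sample SD per metric, plus an Average column.

    Mirrors the standard performance-table layout: metrics as rows,
    algorithms as columns holding ``(mean, sd)`` pairs; the Average column
    averages the algorithm means. Sample (n-1) SD; a single replicate
    reports SD 0. Rounding is left to report writers.
    """
    if not results or any(len(v) == 0 for v in results.values()):
        raise ValueError("need at least one result per algorithm")
    algs = list(results)
    table: dict[tuple[str, str], dict[str, float]] = {}
    for metric in METRIC_ROWS:
        means = []
        for alg in algs:
            vals = np.array([getattr(r, metric) for r in results[alg]], dtype=float)
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            table[(alg, metric)] = {"mean": mean, "sd": sd}
            means.append(mean)
        table[("Average", metric)] = {"mean": float(np.mean(means)),
                                      "sd": float(np.std(means, ddof=1))
                                      if len(means) > 1 else 0.0}
    cols = algs + ["Average"]
    out = pd.DataFrame(
        {c: {m: table[(c, m)]["mean"] for m in METRIC_ROWS} for c in cols})
    sd = pd.DataFrame(
        {c: {m: table[(c, m)]["sd"] for m in METRIC_ROWS} for c in cols})
    out.columns = pd.MultiIndex.from_product([["mean"], cols])
    for c in cols:
        out[("sd", c)] = sd[c]
    return out.loc[list(METRIC_ROWS)]
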