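"""Evaluation metrics for the two tasks, plus multi-run confidence intervals.

Classification is scored over per-instance x per-label binary decisions:
accuracy = (TP+TN)/(TP+FP+TN+FN), micro precision/recall/F1 over the
positive decisions, and subset accuracy (exact label-set match) as the
stricter companion.  Regression uses R² against the truth mean, the
Pearson product-moment correlation, and MSE.  Repeated runs are
summarized as mean ± Student-t 95% half-width.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .records import CANONICAL_SOLVENTS

N_LABELS = len(CANONICAL_SOLVENTS)


@dataclass
class ClassificationReport:
    subset_accuracy: float
    label_accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "subset_accuracy": self.subset_accuracy,
            "label_accuracy": self.label_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "per_class": self.per_class,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def classification_metrics(
    true_sets: Sequence[tuple[str, ...]],
    predicted_sets: Sequence[tuple[str, ...]],
) -> ClassificationReport:
    """Score predicted label sets against the truth on the 10-label grid.

    Every (instance, label) pair is one binary decision; TP/TN/FP/FN are
    counted over all of them.  Precision/recall/F1 are micro-averaged, and
    the per-class table carries precision/recall/F1/support per solvent.
    """
    if len(true_sets) != len(predicted_sets):
        raise ValueError(
            f"length mismatch: {len(true_sets)} true vs {len(predicted_sets)} predicted"
        )
    if not true_sets:
        raise ValueError("empty evaluation input")
    tp = np.zeros(N_LABELS)
    fp = np.zeros(N_LABELS)
    fn = np.zeros(N_LABELS)
    tn = np.zeros(N_LABELS)
    exact = 0
    for truth, pred in zip(true_sets, predicted_sets):
        t, p = set(truth), set(pred)
        if t == p:
            exact += 1
        for k, name in enumerate(CANONICAL_SOLVENTS):
            in_t, in_p = name in t, name in p
            if in_t and in_p:
                tp[k] += 1
            elif in_t:
                fn[k] += 1
            elif in_p:
                fp[k] += 1
            else:
                tn[k] += 1
    total = tp.sum() + fp.sum() + fn.sum() + tn.sum()
    precision = _safe_div(tp.sum(), tp.sum() + fp.sum())
    recall = _safe_div(tp.sum(), tp.sum() + fn.sum())
    f1 = _safe_div(2 * precision * recall, precision + recall)
    per_class = {}
    for k, name in enumerate(CANONICAL_SOLVENTS):
        pk = _safe_div(tp[k], tp[k] + fp[k])
        rk = _safe_div(tp[k], tp[k] + fn[k])
        per_class[name] = {
            "precision": pk,
            "recall": rk,
            "f1": _safe_div(2 * pk * rk, pk + rk),
            "support": int(tp[k] + fn[k]),
        }
    return ClassificationReport(
        subset_accuracy=exact / len(true_sets),
        label_accuracy=float((tp.sum() + tn.sum()) / total),
        precision=precision,
        recall=recall,
        f1=f1,
        per_class=per_class,
    )


@dataclass
class RegressionReport:
    r_squared: float
    pearson_r: float
    mse: float

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "pearson_r": self.pearson_r,
            "mse": self.mse,
        }


def regression_metrics(
    true_values: Sequence[float], predicted_values: Sequence[float]
) -> RegressionReport:
    """R² (against the truth mean), Pearson r, and MSE.

    With zero variance in either series the Pearson correlation is
    undefined and reported as NaN with a warning; zero truth variance
    additionally makes R² undefined (NaN) unless predictions are exact.
    """
    y = np.asarray(true_values, dtype=float)
    yhat = np.asarray(predicted_values, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 2:
        raise ValueError("need at least 2 pairs")
    mse = float(np.mean((y - yhat) ** 2))
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r_squared = 1.0 if ss_res == 0.0 else float("nan")
    else:
        r_squared = 1.0 - ss_res / ss_tot
    sy = float(y.std())
    sx = float(yhat.std())
    if sy == 0.0 or sx == 0.0:
        warnings.warn(
            "Pearson correlation undefined for zero-variance input",
            RuntimeWarning,
            stacklevel=2,
        )
        pearson = float("nan")
    else:
        pearson = float(
            np.mean((y - y.mean()) / sy * (yhat - yhat.mean()) / sx)
        )
    return RegressionReport(r_squared=r_squared, pearson_r=pearson, mse=mse)


@dataclass
class RunSummary:
    """Per-metric mean ± 95% t-interval half-width over repeated runs."""

    per_run: dict
    mean: dict
    half_width: dict
    confidence: float

    def format(self, metric: str, digits: int = 3) -> str:
        hw = self.half_width.get(metric)
        if hw is None:
            return f"{self.mean[metric]:.{digits}f}"
        return f"{self.mean[metric]:.{digits}f} ± {hw:.{digits}f}"


def summarize_runs(
    reports: Sequence[ClassificationReport | RegressionReport | dict],
    confidence: float = 0.95,
) -> RunSummary:
    """Aggregate repeated evaluation runs into mean ± t-interval half-width.

    The half-width is t_{1-(1-c)/2, n-1} * s / sqrt(n) with the sample
    standard deviation s; a single run yields means without intervals.
    """
    if not reports:
        raise ValueError("no reports to summarize")
    dicts = [r if isinstance(r, dict) else r.to_dict() for r in reports]
    metrics = [
        k for k, v in dicts[0].items() if isinstance(v, (int, float))
    ]
    per_run = {m: [d[m] for d in dicts] for m in metrics}
    mean = {m: float(np.mean(v)) for m, v in per_run.items()}
    n = len(dicts)
    half_width: dict = {}
    if n >= 2:
        t_crit = float(stats.t.ppf(1.0 - (1.0 - confidence) / 2.0, n - 1))
        for m, values in per_run.items():
            s = float(np.std(values, ddof=1))
            half_width[m] = t_crit * s / math.sqrt(n)
    return RunSummary(per_run, mean, half_width, confidence)
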