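"""Confusion-matrix classification metrics and multi-run aggregation.

Rates follow the usual one-vs-rest definitions: accuracy
``(TP+TN)/total``, sensitivity ``TP/(TP+FN)``, specificity
``TN/(FP+TN)``, precision ``TP/(TP+FP)`` and the F-score as their
harmonic mean.  A 0/0 rate is reported as NaN (an undefined marker) and
excluded from averages.  Multi-class problems are macro-averaged over
per-class one-vs-rest tables; accuracy stays the plain fraction correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "rate_metrics",
    "multiclass_metrics",
    "aggregate_runs",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(true_labels, predicted_labels, positive_class) -> ConfusionCounts:
    """One-vs-rest confusion counts against ``positive_class``."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"label vectors disagree in length: {t.shape} vs {p.shape}")
    tpos = t == positive_class
    ppos = p == positive_class
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        fp=int(np.sum(~tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else np.nan


def rate_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision, recall, F-score."""
    if counts.total == 0:
        raise ValueError("cannot compute rates from an empty confusion table")
    acc = (counts.tp + counts.tn) / counts.total
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.fp + counts.tn)
    prec = _ratio(counts.tp, counts.tp + counts.fp)
    rec = sens
    if np.isnan(prec) or np.isnan(rec) or prec + rec == 0.0:
        f = np.nan if (np.isnan(prec) or np.isnan(rec)) else 0.0
    else:
        f = 2.0 * prec * rec / (prec + rec)
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "recall": rec,
        "f_score": f,
    }


def multiclass_metrics(true_labels, predicted_labels, positive_class=None) -> dict[str, float]:
    """Macro-averaged one-vs-rest metrics; plain accuracy.

    For binary problems with an explicit ``positive_class`` the result is
    exactly :func:`rate_metrics` on that class.  Otherwise sensitivity,
    specificity, precision and F-score are averaged over classes, skipping
    NaN (undefined) per-class values.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors disagree in length")
    if positive_class is not None:
        out = rate_metrics(confusion_counts(t, p, positive_class))
        out["accuracy"] = float(np.mean(t == p))
        return out
    classes = np.unique(t)
    per = [rate_metrics(confusion_counts(t, p, c)) for c in classes]
    out = {
        key: float(np.nanmean([m[key] for m in per]))
        for key in ("sensitivity", "specificity", "precision", "recall", "f_score")
    }
    out["accuracy"] = float(np.mean(t == p))
    return out


def aggregate_runs(records: list[dict], n_features: int | None = None) -> dict[str, dict[str, float]]:
    """Mean and sample (n-1) standard deviation of each metric over runs.

    ``records`` are flat metric dicts (e.g. per-run results); NaN entries
    are excluded per-metric.  When ``n_features`` is given and the records
    carry ``n_selected``, the normalized average subset size
    ``mean(n_selected) / n_features`` is reported as ``feat_ratio``
    alongside the raw mean count.
    """
    if not records:
        raise ValueError("aggregate_runs needs at least one record")
    keys = [k for k in records[0] if isinstance(records[0][k], (int, float, np.floating, np.integer))]
    out: dict[str, dict[str, float]] = {}
    for key in keys:
        vals = np.asarray([float(r[key]) for r in records], dtype=float)
        ok = vals[~np.isnan(vals)]
        mean = float(ok.mean()) if ok.size else np.nan
        std = float(ok.std(ddof=1)) if ok.size > 1 else 0.0
        out[key] = {"mean": mean, "std": std}
    if n_features is not None and "n_selected" in out:
        out["feat_ratio"] = {
            "mean": out["n_selected"]["mean"] / n_features,
            "std": out["n_selected"]["std"] / n_features,
        }
    return out
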