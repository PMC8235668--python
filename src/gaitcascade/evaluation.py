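"""Binary and cascade evaluation: confusion-count metrics and rank-based AUC.

Binary metrics follow the standard confusion-count definitions::

    accuracy    = (tp + tn) / (tp + tn + fp + fn)
    precision   = tp / (tp + fp)          (positive predictive value)
    recall      = tp / (tp + fn)          (sensitivity)
    specificity = tn / (tn + fp)
    npv         = tn / (tn + fn)
    f1          = 2 * precision * recall / (precision + recall)

A metric with a zero denominator is reported as undefined (None) and listed
in the report's ``undefined`` set — never coerced to 0.  AUC is the
Mann–Whitney rank statistic (ties counted one half): the probability that a
random positive scores above a random negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from gaitcascade.events import EventLabel


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts must not all be zero")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(
        cls, labels: Sequence[int], predictions: Sequence[int]
    ) -> "ConfusionCounts":
        y = np.asarray(labels, dtype=int)
        yhat = np.asarray(predictions, dtype=int)
        if y.shape != yhat.shape:
            raise ValueError("labels and predictions differ in length")
        return cls(
            tp=int(np.sum((y == 1) & (yhat == 1))),
            tn=int(np.sum((y == 0) & (yhat == 0))),
            fp=int(np.sum((y == 0) & (yhat == 1))),
            fn=int(np.sum((y == 1) & (yhat == 0))),
        )


@dataclass
class MetricsReport:
    """All confusion-count metrics (plus optionally AUC) for one scope.

    Undefined metrics (zero denominator, or AUC without both classes) are
    ``None`` and named in ``undefined``.
    """

    counts: ConfusionCounts
    scope: str = "node"
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    specificity: float | None = None
    npv: float | None = None
    f1: float | None = None
    auc: float | None = None
    undefined: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "counts": {
                "tp": self.counts.tp, "tn": self.counts.tn,
                "fp": self.counts.fp, "fn": self.counts.fn,
            },
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "npv": self.npv,
            "f1": self.f1,
            "auc": self.auc,
            "undefined": sorted(self.undefined),
        }


def _ratio(num: int, den: int):
    return (num / den) if den > 0 else None


def binary_metrics(counts: ConfusionCounts, scope: str = "node") -> MetricsReport:
    """Compute every confusion-count metric, flagging undefined ones."""
    c = counts
    report = MetricsReport(counts=c, scope=scope)
    report.accuracy = _ratio(c.tp + c.tn, c.total)
    report.precision = _ratio(c.tp, c.tp + c.fp)
    report.recall = _ratio(c.tp, c.tp + c.fn)
    report.specificity = _ratio(c.tn, c.tn + c.fp)
    report.npv = _ratio(c.tn, c.tn + c.fn)
    if report.precision is not None and report.recall is not None:
        denom = report.precision + report.recall
        report.f1 = (2 * report.precision * report.recall / denom) if denom > 0 else None
    for name in ("accuracy", "precision", "recall", "specificity", "npv", "f1"):
        if getattr(report, name) is None:
            report.undefined.add(name)
    return report


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based (Mann–Whitney) AUC with ties counted one half.

    Raises ``ValueError`` when only one class is present (AUC undefined).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores differ in length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    pos_rank_sum = ranks[y == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class CascadeReport:
    """Aggregate six-class performance of the full cascade."""

    accuracy: float
    per_event_auc: dict[EventLabel, float | None]
    macro_auc: float | None
    confusion: np.ndarray  # 6x6, rows = truth, cols = prediction
    n: int
    per_event_reports: dict[EventLabel, MetricsReport] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_auc": self.macro_auc,
            "per_event_auc": {str(k): v for k, v in self.per_event_auc.items()},
            "confusion": self.confusion.tolist(),
            "n": self.n,
        }


def cascade_metrics(results: Sequence[tuple[EventLabel, "CascadeResult"]]) -> CascadeReport:
    """Six-class accuracy, per-event one-vs-rest AUC and confusion table.

    Each cascade result carries per-event scores (the product of branch
    probabilities along the path to each leaf); one-vs-rest AUC uses those
    scores.  Events absent from the truth have undefined AUC and are excluded
    from the macro average with a warning.
    """
    if not results:
        raise ValueError("cascade_metrics needs at least one result")
    truths = np.array([int(t) for t, _ in results])
    preds = np.array([int(r.event) for _, r in results])

    n_events = len(EventLabel)
    confusion = np.zeros((n_events, n_events), dtype=int)
    for t, p in zip(truths, preds):
        confusion[t, p] += 1
    accuracy = float(np.mean(truths == preds))

    per_event_auc: dict[EventLabel, float | None] = {}
    per_event_reports: dict[EventLabel, MetricsReport] = {}
    defined: list[float] = []
    for event in EventLabel:
        y = (truths == int(event)).astype(int)
        scores = np.array(
            [r.event_scores.get(event, 0.0) if r.event_scores else 0.0 for _, r in results]
        )
        if y.sum() == 0 or y.sum() == len(y):
            per_event_auc[event] = None
            warnings.warn(
                f"event {event} absent from truth; its one-vs-rest AUC is "
                "undefined and excluded from the macro average",
                stacklevel=2,
            )
        else:
            value = auc(y, scores)
            per_event_auc[event] = value
            defined.append(value)
        yhat = (preds == int(event)).astype(int)
        if y.sum() > 0 or yhat.sum() > 0:
            per_event_reports[event] = binary_metrics(
                ConfusionCounts.from_predictions(y, yhat), scope=f"cascade:{event}"
            )

    macro_auc = float(np.mean(defined)) if defined else None
    return CascadeReport(
        accuracy=accuracy,
        per_event_auc=per_event_auc,
        macro_auc=macro_auc,
        confusion=confusion,
        n=len(results),
        per_event_reports=per_event_reports,
    )


def summarize_binary_reports(
    reports: Mapping[str, MetricsReport]
) -> dict[str, float | None]:
    """Mean of each metric over a set of binary-node reports.

    This is the model-averaged aggregation (one number per metric averaged
    over the five nodes), reported alongside the event-macro cascade metrics;
    the two aggregations answer different questions and are labelled apart.
    """
    out: dict[str, float | None] = {}
    for name in ("accuracy", "precision", "recall", "specificity", "npv", "f1", "auc"):
        values = [getattr(r, name) for r in reports.values() if getattr(r, name) is not None]
        out[f"mean_{name}"] = float(np.mean(values)) if values else None
    return out


def render_metrics_table(reports: Mapping[str, MetricsReport]) -> str:
    """Plain-text table: one column per model, one row per metric."""
    names = list(reports)
    rows = ("accuracy", "auc", "precision", "recall", "f1", "specificity", "npv")
    width = max(12, *(len(n) for n in names)) + 2
    lines = ["".ljust(14) + "".join(n.ljust(width) for n in names)]
    for row in rows:
        cells = []
        for n in names:
            v = getattr(reports[n], row)
            cells.append(("-" if v is None else f"{v:.3f}").ljust(width))
        lines.append(row.ljust(14) + "".join(cells))
    return "\n".join(lines)
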