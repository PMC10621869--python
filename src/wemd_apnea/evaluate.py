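"""Binary classification metrics: accuracy, sensitivity, specificity, F1, kappa.

All percent-scale metrics are computed from the confusion counts:

    Acc  = (TP+TN)/(TP+TN+FP+FN) * 100        Sen = TP/(TP+FN) * 100
    Spec = TN/(TN+FP) * 100                   Precision = TP/(TP+FP) * 100
    F1   = 2*Precision*Sen/(Precision+Sen)

The kappa index (KI) is the chance-corrected agreement
(p_o - p_e) / (100 - p_e) * 100, where the observed agreement p_o equals the
accuracy and the chance agreement p_e comes from the products of the confusion
marginals (Cohen's convention).  KI is reported on the 0-100 scale; zero means
chance-level classification.  Ratios with a zero denominator are reported as
NaN and flagged as undefined, never silently as 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model import MlpModel, predict

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "metrics",
           "evaluate_split", "reports_to_frame"]


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """The five evaluation measures (percent scale) plus kappa bookkeeping."""

    Acc: float
    Sen: float
    Spec: float
    Precision: float
    F1: float
    KI: float
    observed_agreement: float
    chance_agreement: float
    undefined: list[str] = field(default_factory=list)
    task: str = ""
    band: str = ""
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def confusion(labels, predictions, positive_class) -> ConfusionCounts:
    """Tally the confusion counts with the declared positive class."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError(f"length mismatch: {labels.shape} vs {predictions.shape}")
    pos_l = labels == positive_class
    pos_p = predictions == positive_class
    return ConfusionCounts(
        TP=int(np.sum(pos_l & pos_p)),
        TN=int(np.sum(~pos_l & ~pos_p)),
        FP=int(np.sum(~pos_l & pos_p)),
        FN=int(np.sum(pos_l & ~pos_p)),
    )


def _ratio(num: float, den: float, undefined: list[str], name: str) -> float:
    if den == 0:
        undefined.append(name)
        return math.nan
    return 100.0 * num / den


def metrics(c: ConfusionCounts, task: str = "", band: str = "",
            seed: int | None = None) -> MetricsReport:
    """All five measures from one confusion matrix."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list[str] = []
    acc = 100.0 * (c.TP + c.TN) / c.total
    sen = _ratio(c.TP, c.TP + c.FN, undefined, "Sen")
    spec = _ratio(c.TN, c.TN + c.FP, undefined, "Spec")
    prec = _ratio(c.TP, c.TP + c.FP, undefined, "Precision")
    if math.isnan(prec) or math.isnan(sen) or prec + sen == 0:
        undefined.append("F1")
        f1 = math.nan
    else:
        f1 = 2.0 * prec * sen / (prec + sen)
    # chance agreement from the marginal products (per-class, summed)
    n = c.total
    actual_pos, actual_neg = c.TP + c.FN, c.TN + c.FP
    pred_pos, pred_neg = c.TP + c.FP, c.TN + c.FN
    p_e = 100.0 * (actual_pos * pred_pos + actual_neg * pred_neg) / (n * n)
    if p_e == 100.0:
        undefined.append("KI")
        ki = math.nan
    else:
        ki = (acc - p_e) / (100.0 - p_e) * 100.0
    return MetricsReport(Acc=acc, Sen=sen, Spec=spec, Precision=prec, F1=f1,
                         KI=ki, observed_agreement=acc, chance_agreement=p_e,
                         undefined=undefined, task=task, band=band, seed=seed)


def evaluate_split(model: MlpModel, X_test: np.ndarray, y_test,
                   positive_class=None, task: str = "", band: str = "",
                   seed: int | None = None) -> MetricsReport:
    """Predict on a held-out split, then confusion -> metrics."""
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    if positive_class is None:
        positive_class = model.classes[0]
    preds = predict(model, X_test)
    c = confusion(y_test, preds, positive_class)
    return metrics(c, task=task, band=band, seed=seed)


def reports_to_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        d = r.to_dict()
        d["undefined"] = ";".join(d["undefined"])
        rows.append(d)
    return pd.DataFrame(rows)


def write_reports(reports: list[MetricsReport], path: str | Path) -> None:
    """Write reports as CSV (``.csv``) or JSON (anything else)."""
    path = Path(path)
    if path.suffix == ".csv":
        reports_to_frame(reports).to_csv(path, index=False)
    else:
        path.write_text(json.dumps([r.to_dict() for r in reports], indent=2))
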