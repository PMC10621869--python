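"""Hjorth parameters per IMF and the 15-dimensional per-band feature vector.

Hjorth's three descriptors summarize a signal's power and spectral shape in the
time domain:

    activity   = var(y)                      (signal power)
    mobility   = sqrt(var(dy) / var(y))      (mean frequency proxy)
    complexity = mobility(dy) / mobility(y)  (bandwidth proxy)

The derivative is estimated by the first difference; since mobility and
complexity are ratios, the sampling step cancels and is left out.  Variances use
the 1/N convention.  Degenerate inputs (zero variance, e.g. all-zero padded
IMFs) yield 0-valued features with a flag instead of raising, so fixed-shape
feature vectors flow through the pipeline.  Each sub-band of each segment is
represented by 15 features: {activity, mobility, complexity} for each of the
five IMFs, in IMF order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decompose import ImfDecomposition

__all__ = [
    "FeatureVector",
    "activity",
    "mobility",
    "complexity",
    "extract_features",
    "feature_significance",
    "feature_names",
    "features_to_frame",
]

N_FEATURES = 15


def activity(y: np.ndarray) -> float:
    """Signal variance (1/N denominator)."""
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("activity needs at least 2 samples")
    return float(np.var(y))


def mobility(y: np.ndarray) -> float:
    """sqrt(var(first difference) / var(signal)); 0 for a degenerate signal."""
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("mobility needs at least 3 samples")
    v = np.var(y)
    if v == 0:
        return 0.0
    return float(np.sqrt(np.var(np.diff(y)) / v))


def complexity(y: np.ndarray) -> float:
    """mobility(first difference) / mobility(signal); 0 when degenerate."""
    y = np.asarray(y, dtype=float)
    if len(y) < 4:
        raise ValueError("complexity needs at least 4 samples")
    m_y = mobility(y)
    if m_y == 0:
        return 0.0
    dy = np.diff(y)
    if np.var(dy) == 0:
        return 0.0
    return float(mobility(dy) / m_y)


def feature_names() -> list[str]:
    return [f"imf{m}_{p}" for m in range(5)
            for p in ("activity", "mobility", "complexity")]


@dataclass
class FeatureVector:
    """The 15 Hjorth values of one sub-band of one segment."""

    values: np.ndarray
    band: str = ""
    label: str = ""
    segment_id: str = ""
    degenerate_imfs: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, "
                             f"got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def extract_features(decomposition: ImfDecomposition, label: str = "",
                     segment_id: str = "") -> FeatureVector:
    """Assemble the 15-feature vector (IMF0..IMF4 x activity/mobility/complexity).

    Padded (all-zero) IMFs contribute a (0, 0, 0) triple and are flagged.
    """
    if len(decomposition.imfs) != 5:
        raise ValueError(f"expected 5 IMF slots, got {len(decomposition.imfs)}")
    values = []
    degenerate = []
    for m, imf in enumerate(decomposition.imfs):
        if np.var(imf) == 0:
            values.extend([0.0, 0.0, 0.0])
            degenerate.append(m)
        else:
            values.extend([activity(imf), mobility(imf), complexity(imf)])
    return FeatureVector(values=np.asarray(values),
                         band=decomposition.source_band, label=label,
                         segment_id=segment_id, degenerate_imfs=degenerate)


def features_to_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Feature table: one row per vector, columns segment_id, band, label, f01..f15."""
    cols = [f"f{i + 1:02d}" for i in range(N_FEATURES)]
    rows = [{"segment_id": v.segment_id, "band": v.band, "label": v.label,
             **dict(zip(cols, v.values))} for v in vectors]
    return pd.DataFrame(rows, columns=["segment_id", "band", "label", *cols])


def feature_significance(table: pd.DataFrame | list[FeatureVector],
                         alpha: float = 0.01) -> pd.DataFrame:
    """Per-feature two-sample rank test (Mann-Whitney U) between the two classes.

    Reports a p-value and a pass flag at ``alpha`` for each of the 15 features.
    The screen is purely descriptive: no feature is dropped based on it.
    """
    if not isinstance(table, pd.DataFrame):
        table = features_to_frame(table)
    labels = table["label"].unique()
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(labels)}")
    cols = [c for c in table.columns if c.startswith("f") and c[1:].isdigit()]
    g0 = table[table["label"] == labels[0]]
    g1 = table[table["label"] == labels[1]]
    if len(g0) < 5 or len(g1) < 5:
        raise ValueError("need >=5 samples per class for the rank test")
    records = []
    for c in cols:
        a, b = g0[c].to_numpy(), g1[c].to_numpy()
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        records.append({"feature": c, "p_value": p, "significant": p < alpha})
    return pd.DataFrame(records)
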