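"""End-to-end orchestration: segments -> features -> train/evaluate per band.

The per-segment stage order is fixed: 30 Hz low-pass FIR -> fractional
down-sampling to 64 Hz -> 4-level wavelet split -> EMD of each selected band ->
15 Hjorth features per band.  An experiment runs one binary task
(A_vs_B, A_vs_C, B_vs_C or apnea_vs_normal) over a chosen set of bands,
training one classifier per band on a train/test split and reporting the five
evaluation measures per band.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import decompose, features, multirate
from .evaluate import MetricsReport, evaluate_split, reports_to_frame
from .features import FeatureVector, extract_features, features_to_frame
from .model import MlpConfig, train
from .synthetic import (CLASS_MODULATION_DEPTHS, LabeledSegment,
                        SyntheticConfig, generate_dataset)

__all__ = ["ExperimentConfig", "run_pipeline", "run_experiment",
            "split_indices", "TASKS"]

logger = logging.getLogger(__name__)

# task name -> (positive class, negative class)
TASKS = {
    "A_vs_B": ("A", "B"),
    "A_vs_C": ("A", "C"),
    "B_vs_C": ("B", "C"),
    "apnea_vs_normal": ("apnea", "normal"),
}

BAND_KEYS = {"Delta": "a4", "Theta": "d4", "Alpha": "d3", "Beta": "d2"}


@dataclass
class ExperimentConfig:
    task: str = "A_vs_C"
    bands: tuple[str, ...] = ("Delta", "Theta", "Alpha", "Beta")
    split: str = "segment"            # "segment" (stratified) or "record"
    train_fraction: float = 0.5
    seed: int = 0
    n_per_class: int = 100
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    mlp: MlpConfig = field(default_factory=MlpConfig)
    wavelet: str = "db4"
    downsample_factor: float = 1.5625

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; one of {list(TASKS)}")
        unknown = set(self.bands) - set(BAND_KEYS)
        if unknown:
            raise ValueError(f"unknown bands {sorted(unknown)}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    def config_hash(self) -> str:
        blob = json.dumps({**asdict(self),
                           "bands": list(self.bands)}, sort_keys=True,
                          default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(segment: LabeledSegment, wavelet: str = "db4",
                 D: float = 1.5625,
                 fir: multirate.FirFilter | None = None
                 ) -> dict[str, FeatureVector]:
    """Process one segment through every stage; one feature vector per band."""
    if fir is None:
        fir = multirate.design_lowpass_fir(fs=segment.fs)
    spec = multirate.ResampleSpec(D=D, fs_in=segment.fs, f_max=fir.fc)
    try:
        x_n = multirate.apply_fir(fir, segment.samples)
        yd_n = multirate.fractional_downsample(x_n, spec.D)
        bands = decompose.dwt_subbands(yd_n, wavelet=wavelet)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed on segment {segment.record_id}/"
            f"{segment.segment_index}: {exc}") from exc
    out: dict[str, FeatureVector] = {}
    for name, key in BAND_KEYS.items():
        coeffs = bands.selected()[key]
        if np.var(coeffs) == 0:
            imfs = decompose.ImfDecomposition(
                imfs=[np.zeros_like(coeffs)] * 5, residue=coeffs.copy(),
                source_band=name, sift_counts=[0] * 5, padded=True)
        else:
            imfs = decompose.emd(coeffs, source_band=name)
        out[name] = extract_features(
            imfs, label=segment.label,
            segment_id=f"{segment.record_id}/{segment.segment_index}")
    return out


def split_indices(labels, record_ids, mode: str, train_fraction: float,
                  seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Train/test index split.

    ``"segment"``: stratified by label over individual segments.
    ``"record"``: whole records assigned to one side only, so no record
    contributes segments to both train and test.
    """
    labels = np.asarray(labels)
    record_ids = np.asarray(record_ids)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    if mode == "segment":
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            n_train = max(1, int(round(train_fraction * len(idx))))
            train_idx.extend(idx[:n_train])
    elif mode == "record":
        for cls in np.unique(labels):
            recs = np.unique(record_ids[labels == cls])
            rng.shuffle(recs)
            n_train = max(1, int(round(train_fraction * len(recs))))
            chosen = set(recs[:n_train])
            train_idx.extend(i for i in np.flatnonzero(labels == cls)
                             if record_ids[i] in chosen)
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    train_mask = np.zeros(len(labels), dtype=bool)
    train_mask[train_idx] = True
    return np.flatnonzero(train_mask), np.flatnonzero(~train_mask)


def _synthetic_segments(config: ExperimentConfig) -> list[LabeledSegment]:
    pos, neg = TASKS[config.task]
    if config.task == "apnea_vs_normal":
        classes = {"apnea": CLASS_MODULATION_DEPTHS["A"], "normal": 0.0}
    else:
        classes = {c: CLASS_MODULATION_DEPTHS[c] for c in (pos, neg)}
    syn = SyntheticConfig(**{**asdict(config.synthetic), "seed": config.seed})
    return generate_dataset(config.n_per_class, syn, classes=classes)


def run_experiment(config: ExperimentConfig,
                   segments: list[LabeledSegment] | None = None
                   ) -> pd.DataFrame:
    """Run one binary task over the selected bands; one metrics row per band.

    When ``segments`` is None a balanced synthetic dataset for the task is
    generated.  A band whose features are degenerate for every segment is
    reported as a failed row and the run continues.
    """
    if segments is None:
        segments = _synthetic_segments(config)
    pos, neg = TASKS[config.task]
    segments = [s for s in segments if s.label in (pos, neg)]
    if not segments:
        raise ValueError(f"no segments with labels {pos}/{neg}")

    fir = multirate.design_lowpass_fir(fs=segments[0].fs)
    per_band: dict[str, list[FeatureVector]] = {b: [] for b in config.bands}
    for seg in segments:
        vecs = run_pipeline(seg, wavelet=config.wavelet,
                            D=config.downsample_factor, fir=fir)
        for b in config.bands:
            per_band[b].append(vecs[b])

    labels = np.asarray([s.label for s in segments])
    record_ids = np.asarray([s.record_id for s in segments])
    train_idx, test_idx = split_indices(labels, record_ids, config.split,
                                        config.train_fraction, config.seed)

    cfg_hash = config.config_hash()
    reports: list[MetricsReport] = []
    rows_failed: list[str] = []
    for b in config.bands:
        X = np.vstack([v.values for v in per_band[b]])
        if np.all(X.std(axis=0) == 0):
            logger.warning("band %s: degenerate features for all segments", b)
            rows_failed.append(b)
            continue
        mlp_cfg = MlpConfig(**{**asdict(config.mlp), "seed": config.seed})
        mdl, _ = train(X[train_idx], labels[train_idx], mlp_cfg)
        rep = evaluate_split(mdl, X[test_idx], labels[test_idx],
                             positive_class=pos, task=config.task, band=b,
                             seed=config.seed)
        reports.append(rep)

    frame = reports_to_frame(reports)
    if not frame.empty:
        frame["config_hash"] = cfg_hash
        frame["status"] = "ok"
    for b in rows_failed:
        frame = pd.concat([frame, pd.DataFrame([{
            "task": config.task, "band": b, "seed": config.seed,
            "config_hash": cfg_hash, "status": "failed"}])],
            ignore_index=True)
    return frame


def featurize_segments(segments: list[LabeledSegment],
                       bands: tuple[str, ...] = ("Delta", "Theta", "Alpha", "Beta"),
                       wavelet: str = "db4", D: float = 1.5625) -> pd.DataFrame:
    """Feature table over all segments and bands (for the CLI featurize step)."""
    if not segments:
        raise ValueError("no segments to featurize")
    fir = multirate.design_lowpass_fir(fs=segments[0].fs)
    vectors: list[FeatureVector] = []
    for seg in segments:
        vecs = run_pipeline(seg, wavelet=wavelet, D=D, fir=fir)
        vectors.extend(vecs[b] for b in bands)
    return features_to_frame(vectors)
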