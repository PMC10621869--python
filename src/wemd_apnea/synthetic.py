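"""Synthetic single-lead ECG generator with an apnea-like heart-rate modulation class.

The generator produces 60-second, 100 Hz segments whose beat-to-beat timing is
controlled by an instantaneous heart-rate profile.  The "apnea-like" class adds a
slow sinusoidal bradycardia--tachycardia cycle to the heart rate, mimicking the
cyclic variation that accompanies repetitive obstructive events; the normal class
keeps the rate constant.  Beat morphology is a fixed sum of five Gaussian bumps
(P, Q, R, S, T) per beat, with the R peak normalized to amplitude 1, plus optional
white measurement noise and 50 Hz power-line interference.

This is deliberately a statistical surrogate, not a physiological simulator: it
reproduces the sampling rate, segment length, labeling scheme and class-contrast
structure the downstream pipeline assumes, nothing more.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "SyntheticConfig",
    "LabeledSegment",
    "generate_ecg",
    "generate_apnea_segment",
    "generate_dataset",
    "write_segment_csv",
    "read_segment_csv",
    "CLASS_MODULATION_DEPTHS",
]

# Record-class contrast: A = pronounced cyclic HR modulation, B = intermediate,
# C = none.  These depths define the simulated study conditions.
CLASS_MODULATION_DEPTHS = {"A": 0.4, "B": 0.2, "C": 0.0}

# (phase offset in seconds relative to R, amplitude, Gaussian width in seconds)
_BEAT_BUMPS = {
    "P": (-0.200, 0.15, 0.045),
    "Q": (-0.035, -0.12, 0.012),
    "R": (0.000, 1.00, 0.020),
    "S": (0.035, -0.20, 0.014),
    "T": (0.220, 0.30, 0.070),
}


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic ECG segment.

    fs : sampling rate, Hz.
    duration_s : segment length, seconds.
    heart_rate_bpm : mean heart rate, beats/minute.
    hr_modulation_depth : fractional amplitude of the cyclic heart-rate
        modulation, in [0, 1]; 0 disables it.
    hr_modulation_period_s : period of the apnea-like cycle, seconds.
    noise_sd : white-noise standard deviation relative to R amplitude 1.
    powerline_amp : amplitude of an additive 50 Hz interference tone.
    seed : RNG seed; the signal is a deterministic function of (config, seed).
    """

    fs: float = 100.0
    duration_s: float = 60.0
    heart_rate_bpm: float = 60.0
    hr_modulation_depth: float = 0.0
    hr_modulation_period_s: float = 45.0
    noise_sd: float = 0.05
    powerline_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if not 0.0 <= self.hr_modulation_depth <= 1.0:
            raise ValueError("hr_modulation_depth must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart_rate_bpm must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


@dataclass
class LabeledSegment:
    """One labeled window of synthetic or real ECG."""

    samples: np.ndarray
    fs: float
    label: str
    segment_index: int = 0
    record_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


def _beat_times(config: SyntheticConfig) -> np.ndarray:
    """Beat onset times from the (possibly modulated) instantaneous heart rate.

    The instantaneous rate f(t) = (bpm/60) * (1 + depth*sin(2*pi*t/T)) is
    integrated on a fine grid; a beat fires at every integer crossing of the
    accumulated phase.
    """
    dt = 1.0 / (4.0 * config.fs)
    # extend past the segment so edge beats have complete morphology
    t = np.arange(0.0, config.duration_s + 2.0, dt)
    f0 = config.heart_rate_bpm / 60.0
    if config.hr_modulation_depth > 0:
        rate = f0 * (1.0 + config.hr_modulation_depth
                     * np.sin(2.0 * np.pi * t / config.hr_modulation_period_s))
    else:
        rate = np.full_like(t, f0)
    phase = np.concatenate(([0.0], np.cumsum(rate[:-1] * dt)))
    n_beats = int(np.floor(phase[-1]))
    # invert phase(t) at integer phases; phase is strictly increasing
    return np.interp(np.arange(n_beats + 1, dtype=float), phase, t)


def generate_ecg(config: SyntheticConfig) -> LabeledSegment:
    """Generate one normal-class synthetic ECG segment.

    The waveform is a superposition of five localized Gaussian bumps per beat at
    fixed phase offsets, sampled at ``config.fs``; R-peak amplitude is 1 before
    noise.  Deterministic given the seed.
    """
    return _generate(config, label="normal", depth_override=0.0)


def generate_apnea_segment(config: SyntheticConfig) -> LabeledSegment:
    """Generate one apnea-class segment with cyclic heart-rate modulation.

    If the configured modulation depth is zero there is no class signal; a
    warning is issued and a normal-class segment is returned instead.
    """
    if config.hr_modulation_depth == 0:
        warnings.warn(
            "hr_modulation_depth is 0: no apnea-like modulation possible; "
            "returning a normal-class segment",
            stacklevel=2,
        )
        return generate_ecg(config)
    return _generate(config, label="apnea", depth_override=None)


def _generate(config: SyntheticConfig, label: str,
              depth_override: float | None) -> LabeledSegment:
    if depth_override is not None and depth_override != config.hr_modulation_depth:
        cfg = SyntheticConfig(**{**asdict(config),
                                 "hr_modulation_depth": depth_override})
    else:
        cfg = config
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    beats = _beat_times(cfg)
    signal = np.zeros(n)
    for t_r in beats:
        for offset, amp, width in _BEAT_BUMPS.values():
            center = t_r + offset
            # Gaussians are negligible beyond 5 widths; restrict the support
            lo = np.searchsorted(t, center - 5 * width)
            hi = np.searchsorted(t, center + 5 * width)
            if hi > lo:
                signal[lo:hi] += amp * np.exp(
                    -0.5 * ((t[lo:hi] - center) / width) ** 2)
    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=n)
    if cfg.powerline_amp > 0:
        signal = signal + cfg.powerline_amp * np.sin(2.0 * np.pi * 50.0 * t)
    return LabeledSegment(samples=signal, fs=cfg.fs, label=label)


def generate_dataset(n_per_class: int,
                     config: SyntheticConfig | None = None,
                     classes: dict[str, float] | None = None) -> list[LabeledSegment]:
    """Generate a balanced labeled dataset.

    Parameters
    ----------
    n_per_class : segments per class, >= 1.
    config : template configuration; per-segment seeds are derived from
        ``config.seed`` with a counter-based scheme (``SeedSequence`` spawn
        keys), so the dataset is reproducible independent of generation order.
    classes : mapping class label -> modulation depth; defaults to the A/B/C
        record classes with depths 0.4 / 0.2 / 0.0.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if config is None:
        config = SyntheticConfig()
    if classes is None:
        classes = dict(CLASS_MODULATION_DEPTHS)

    segments: list[LabeledSegment] = []
    counter = 0
    for label in sorted(classes):
        depth = classes[label]
        for i in range(n_per_class):
            ss = np.random.SeedSequence(config.seed, spawn_key=(counter,))
            seg_seed = int(ss.generate_state(1)[0] % (2**31))
            counter += 1
            cfg = SyntheticConfig(**{**asdict(config),
                                     "hr_modulation_depth": depth,
                                     "seed": seg_seed})
            if depth > 0:
                seg = generate_apnea_segment(cfg)
            else:
                seg = generate_ecg(cfg)
            seg.label = label
            seg.segment_index = i
            seg.record_id = f"syn-{label}-{i:04d}"
            segments.append(seg)
    return segments


def write_segment_csv(segment: LabeledSegment, path: str | Path,
                      config: SyntheticConfig | None = None) -> None:
    """Write a segment to CSV (sample_index, amplitude) with a JSON sidecar."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_index", "amplitude"])
        for i, v in enumerate(segment.samples):
            writer.writerow([i, repr(float(v))])
    meta = {
        "fs": segment.fs,
        "label": segment.label,
        "segment_index": segment.segment_index,
        "record_id": segment.record_id,
    }
    if config is not None:
        meta["config"] = asdict(config)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_segment_csv(path: str | Path) -> LabeledSegment:
    """Read a segment written by :func:`write_segment_csv`."""
    path = Path(path)
    samples = np.loadtxt(path, delimiter=",", skiprows=1, usecols=1)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return LabeledSegment(samples=samples, fs=meta["fs"], label=meta["label"],
                          segment_index=meta.get("segment_index", 0),
                          record_id=meta.get("record_id", "unknown"))
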