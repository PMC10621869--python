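"""Reading and windowing of single-lead ECG records.

Records are cut into fixed non-overlapping 60-second windows with a rectangular
window of ones (the windowing is an identity on the retained samples; a trailing
partial window is dropped).  Record-level severity classes follow the
apnea--hypopnea index (AHI): A for AHI >= 10, B for 5 <= AHI < 10, C for AHI < 5.
Per-minute apnea/normal annotations, when present, attach to the matching window.

A small self-contained WFDB reader/writer is included: header (.hea) parsing,
format-16 (little-endian int16) signal files, and MIT-format annotation files
restricted to the two annotation codes the apnea annotations use (N = normal
minute, A = apnea minute).  CSV input (one sample per line, ``# fs=<Hz>`` header
comment) is supported as a plain-text alternative.
"""

from __future__ import annotations

import logging
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synthetic import LabeledSegment

__all__ = [
    "EcgRecord",
    "WindowFunction",
    "segment_record",
    "assign_record_class",
    "read_csv_record",
    "write_csv_record",
    "read_wfdb_record",
    "write_wfdb_record",
]

logger = logging.getLogger(__name__)

# MIT annotation type codes used by per-minute apnea annotations
_ANN_NORMAL = 1   # symbol 'N'
_ANN_APNEA = 8    # symbol 'A'


@dataclass
class EcgRecord:
    """A digitized single-lead ECG record with optional annotations."""

    y_n: np.ndarray
    fs: float
    record_id: str = ""
    minute_labels: list[str] | None = None
    record_class: str | None = None

    def __post_init__(self) -> None:
        self.y_n = np.asarray(self.y_n, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.minute_labels is not None:
            max_minutes = int(np.ceil(len(self.y_n) / (60.0 * self.fs)))
            if len(self.minute_labels) > max_minutes:
                raise ValueError(
                    f"{len(self.minute_labels)} minute labels for a record of "
                    f"at most {max_minutes} minutes")


@dataclass
class WindowFunction:
    """Rectangular window: a vector of ones spanning tau seconds."""

    fs: float
    tau: float = 60.0
    s_n: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.s_n = np.ones(int(round(self.fs * self.tau)))


def segment_record(record: EcgRecord, tau: float = 60.0) -> list[LabeledSegment]:
    """Cut a record into consecutive non-overlapping tau-second windows.

    Window k covers samples [k*w, (k+1)*w) with w = round(fs*tau); a trailing
    partial window is dropped.  Each segment's label is the matching per-minute
    annotation when available, else the record class, else "unlabeled".
    """
    w = int(round(record.fs * tau))
    n_windows = len(record.y_n) // w
    if n_windows == 0:
        warnings.warn(
            f"record {record.record_id!r} shorter than one {tau}-s window; "
            "returning no segments", stacklevel=2)
        return []
    window = WindowFunction(fs=record.fs, tau=tau)
    segments = []
    for k in range(n_windows):
        ys = record.y_n[k * w:(k + 1) * w] * window.s_n
        if record.minute_labels is not None and k < len(record.minute_labels):
            label = record.minute_labels[k]
        elif record.record_class is not None:
            label = record.record_class
        else:
            label = "unlabeled"
        segments.append(LabeledSegment(samples=ys, fs=record.fs, label=label,
                                       segment_index=k,
                                       record_id=record.record_id))
    return segments


def assign_record_class(ahi: float) -> str:
    """Map an AHI score (events/hour) to record class A, B or C."""
    if ahi < 0:
        raise ValueError(f"AHI must be non-negative, got {ahi}")
    if ahi >= 10:
        return "A"
    if ahi >= 5:
        return "B"
    return "C"


# ---------------------------------------------------------------------------
# CSV I/O

def read_csv_record(path: str | Path, fs: float | None = None,
                    record_id: str | None = None) -> EcgRecord:
    """Read a plain-text record: one amplitude per line, ``# fs=<Hz>`` comment.

    An explicit ``fs`` argument overrides the header comment.
    """
    path = Path(path)
    header_fs = None
    samples: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("fs"):
                    header_fs = float(body.split("=", 1)[1])
                continue
            samples.append(float(line.split(",")[-1]))
    if fs is None:
        fs = header_fs
    if fs is None:
        raise ValueError(f"{path}: no sampling rate ('# fs=...' header) found "
                         "and none supplied")
    return EcgRecord(y_n=np.asarray(samples), fs=fs,
                     record_id=record_id or path.stem)


def write_csv_record(record: EcgRecord, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs}\n")
        for v in record.y_n:
            fh.write(f"{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Minimal WFDB I/O (format 16, single segment, optional apnea annotations)

def read_wfdb_record(path: str | Path,
                     annotator: str = "apn") -> EcgRecord:
    """Read a WFDB record (.hea + format-16 .dat) and optional annotations.

    ``path`` is the record path without extension.  If a multi-channel record
    is encountered the first channel is used and a note is logged.  When a
    ``<record>.<annotator>`` file exists, its N/A annotations are mapped to
    per-minute normal/apnea labels.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise IOError(f"missing WFDB header file: {hea}")
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_fields = lines[0].split()
    record_name = rec_fields[0]
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    if n_sig > 1:
        logger.info("record %s has %d channels; using the first", record_name, n_sig)
    sig_fields = lines[1].split()
    dat_name, fmt = sig_fields[0], sig_fields[1]
    if fmt.split("x")[0] != "16":
        raise IOError(f"unsupported WFDB signal format {fmt!r} in {hea} "
                      "(only format 16 is supported)")
    gain = 200.0
    baseline = 0
    if len(sig_fields) > 2:
        gain_field = sig_fields[2]
        if "(" in gain_field:
            gain_part, base_part = gain_field.split("(")
            gain = float(gain_part) if gain_part else 200.0
            baseline = int(base_part.rstrip(")").split("/")[0])
        else:
            gain = float(gain_field.split("/")[0])
    if gain == 0:
        gain = 200.0
    dat = path.parent / dat_name
    if not dat.exists():
        raise IOError(f"missing WFDB signal file: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    if n_sig > 1:
        raw = raw[: (len(raw) // n_sig) * n_sig].reshape(-1, n_sig)[:, 0]
    samples = (raw.astype(float) - baseline) / gain

    minute_labels = None
    ann = path.with_suffix(f".{annotator}")
    if ann.exists():
        minute_labels = _read_annotation_labels(ann)
    return EcgRecord(y_n=samples, fs=fs, record_id=record_name,
                     minute_labels=minute_labels)


def _read_annotation_labels(path: Path) -> list[str]:
    """Decode an MIT annotation file into per-minute apnea/normal labels."""
    data = path.read_bytes()
    labels: list[str] = []
    i = 0
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:          # EOF
            break
        if code == 59:                           # SKIP: 4-byte time follows
            i += 4
            continue
        if code in (60, 61, 62):                 # NUM / SUB / CHN modifiers
            continue
        if code == 63:                           # AUX: interval bytes, even-padded
            i += interval + (interval & 1)
            continue
        if code == _ANN_APNEA:
            labels.append("apnea")
        elif code == _ANN_NORMAL:
            labels.append("normal")
        else:
            logger.warning("%s: ignoring annotation code %d", path, code)
    return labels


def write_wfdb_record(record: EcgRecord, path: str | Path,
                      gain: float = 200.0, annotator: str = "apn") -> None:
    """Write a record as WFDB header + format-16 signal (+ annotations).

    Amplitudes are quantized to ``round(value * gain)`` 16-bit integers, so a
    read-back differs from the original by at most 0.5/gain per sample.
    """
    path = Path(path)
    name = path.name
    digital = np.clip(np.round(record.y_n * gain), -32768, 32767).astype("<i2")
    path.with_suffix(".hea").write_text(
        f"{name} 1 {record.fs:g} {len(digital)}\n"
        f"{name}.dat 16 {gain:g}(0) 16 0 {int(digital[0]) if len(digital) else 0} 0 0 ECG\n"
    )
    digital.tofile(path.with_suffix(".dat"))
    if record.minute_labels is not None:
        _write_annotation_labels(path.with_suffix(f".{annotator}"),
                                 record.minute_labels, record.fs)


def _write_annotation_labels(path: Path, labels: list[str], fs: float) -> None:
    samples_per_minute = int(round(60 * fs))
    out = bytearray()
    prev = 0
    for k, label in enumerate(labels):
        t = k * samples_per_minute
        delta = t - prev
        prev = t
        if delta > 1023:                         # SKIP escape for long gaps
            out += struct.pack("<H", 59 << 10)
            # 4-byte interval, PDP-11 order: high 16 bits first, each LE
            out += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        code = _ANN_APNEA if label == "apnea" else _ANN_NORMAL
        out += struct.pack("<H", (code << 10) | delta)
    out += struct.pack("<H", 0)                  # EOF
    path.write_bytes(bytes(out))
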