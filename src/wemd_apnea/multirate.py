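"""Multirate front end: 30 Hz equiripple low-pass and fractional decimation.

Each 100 Hz segment is band-limited to the ECG's useful spectrum (0--30 Hz) with
a linear-phase FIR filter designed by the Parks--McClellan (Remez exchange)
algorithm, then fractionally down-sampled by D = 1.5625 to an effective 64 Hz
rate with a cubic-spline resampler.  The decimation factor must respect the
anti-aliasing bound D <= F_S1 / F_Nyq with F_Nyq = 2 * f_max = 60 Hz; at the
default rates the bound is 100/60 = 1.6667, which D = 1.5625 satisfies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

__all__ = [
    "FirFilter",
    "ResampleSpec",
    "design_lowpass_fir",
    "apply_fir",
    "fractional_downsample",
]


@dataclass
class FirFilter:
    """Linear-phase low-pass FIR filter and its design parameters."""

    h_k: np.ndarray
    fs: float
    fc: float
    passband_edge: float
    stopband_edge: float
    attenuation_db: float

    def __post_init__(self) -> None:
        self.h_k = np.asarray(self.h_k, dtype=float)
        if self.fs < 2 * self.fc:
            raise ValueError(
                f"sampling rate {self.fs} violates fs >= 2*fc for fc={self.fc}")

    @property
    def n_taps(self) -> int:
        return len(self.h_k)

    def frequency_response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Complex response H(f) at the given frequencies (Hz)."""
        _, h = sps.freqz(self.h_k, worN=np.atleast_1d(np.asarray(freqs_hz, float)),
                         fs=self.fs)
        return h

    def to_text(self, path: str | Path) -> None:
        np.savetxt(Path(path), self.h_k, fmt="%.18e")


@dataclass
class ResampleSpec:
    """Fractional decimation spec with the anti-aliasing guard built in."""

    D: float = 1.5625
    fs_in: float = 100.0
    f_max: float = 30.0

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError("D must be >= 1 (this stage only decimates)")
        bound = self.fs_in / self.f_nyq
        if self.D > bound:
            raise ValueError(
                f"D={self.D} exceeds the anti-aliasing bound fs/F_Nyq="
                f"{bound:.4f}; decimating this far would alias")

    @property
    def f_nyq(self) -> float:
        return 2.0 * self.f_max

    @property
    def output_fs(self) -> float:
        return self.fs_in / self.D


def design_lowpass_fir(fs: float = 100.0, fc: float = 30.0, *,
                       n_taps: int = 101,
                       passband_edge: float | None = None,
                       stopband_edge: float = 35.0,
                       attenuation_db: float = 40.0) -> FirFilter:
    """Design an equiripple linear-phase low-pass FIR with the Remez exchange.

    The defaults (101 taps, passband to 30 Hz, stopband from 35 Hz) give well
    over the required 40 dB stopband attenuation at a 100 Hz rate.  Raises if
    the achieved stopband attenuation falls short of ``attenuation_db``.
    """
    if not fc < fs / 2:
        raise ValueError(f"cut-off {fc} must be below Nyquist {fs / 2}")
    if passband_edge is None:
        passband_edge = fc
    h = sps.remez(n_taps, [0, passband_edge, stopband_edge, fs / 2], [1, 0], fs=fs)
    filt = FirFilter(h_k=h, fs=fs, fc=fc, passband_edge=passband_edge,
                     stopband_edge=stopband_edge, attenuation_db=attenuation_db)
    # verify the spec is actually met at this order
    f_check = np.linspace(stopband_edge, fs / 2, 256)
    worst = np.max(np.abs(filt.frequency_response(f_check)))
    if 20 * np.log10(worst) > -attenuation_db:
        raise ValueError(
            f"{n_taps}-tap design only reaches {-20 * np.log10(worst):.1f} dB "
            f"stopband attenuation (< {attenuation_db} dB); increase n_taps")
    return filt


def apply_fir(filt: FirFilter, samples: np.ndarray,
              compensate_delay: bool = True) -> np.ndarray:
    """Convolve a segment with the filter: x_n = sum_k h_k * ys_{n-k}.

    With ``compensate_delay`` the output is shifted by the (M-1)/2 group delay
    of the linear-phase filter and truncated to the input length, zero-padding
    the edges, so sample n of the output aligns with sample n of the input.
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) < filt.n_taps:
        raise ValueError(
            f"segment length {len(samples)} shorter than filter ({filt.n_taps} taps)")
    full = np.convolve(samples, filt.h_k, mode="full")
    if not compensate_delay:
        return full
    delay = (filt.n_taps - 1) // 2
    return full[delay:delay + len(samples)]


def fractional_downsample(x_n: np.ndarray, D: float = 1.5625) -> np.ndarray:
    """Decimate by a fractional factor with a natural cubic-spline resampler.

    The interpolant of x_n on the integer grid is evaluated at t = n*D for
    n = 0, 1, ..., floor((N-1)/D), i.e. yd_n = x(D*n); the output grid is
    anchored at sample 0.
    """
    x_n = np.asarray(x_n, dtype=float)
    if D < 1:
        raise ValueError("D must be >= 1 (this stage only decimates)")
    n_in = len(x_n)
    if n_in < 2:
        raise ValueError("need at least 2 samples to resample")
    n_out = int(np.floor((n_in - 1) / D)) + 1
    if D == 1.0:
        return x_n.copy()
    spline = CubicSpline(np.arange(n_in), x_n, bc_type="natural")
    return spline(np.arange(n_out) * D)
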