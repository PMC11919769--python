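"""The recording-chain filters applied to synthetic traces.

The measurement chain is an in-line four-pole low-pass Bessel filter
(80 dB per decade, 5 kHz) ahead of the digitizer, followed by a 20 Hz
digital Bessel filter for analysis, with Savitzky-Golay smoothing (400 ms
window, polynomial order 1) used for display-level moving averages.

Digital Bessel filters are obtained by bilinear transform of the analog
prototype with magnitude normalization (-3 dB at the cutoff, matching the
instrument convention) and are applied causally (forward only), as the
hardware filter is causal.  DC gain is renormalized to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .simulate import Trace

__all__ = [
    "FilterSpec",
    "bessel_sos",
    "apply_filter",
    "bessel_lowpass",
    "moving_average_sg",
    "decimate",
    "filter_chain",
    "noise_bandwidth_fraction",
    "standard_chain",
]


@dataclass(frozen=True)
class FilterSpec:
    """One stage of the recording chain."""

    kind: str                      # bessel_lowpass | savitzky_golay | decimate
    cutoff_hz: Optional[float] = None
    order: int = 4
    window_s: Optional[float] = None
    factor: Optional[int] = None
    stage: str = ""

    def describe(self) -> str:
        if self.kind == "bessel_lowpass":
            return f"bessel_lowpass(order={self.order}, cutoff={self.cutoff_hz:g} Hz)"
        if self.kind == "savitzky_golay":
            return f"savitzky_golay(window={self.window_s:g} s, polyorder=1)"
        if self.kind == "decimate":
            return f"decimate(factor={self.factor})"
        return self.kind


def bessel_sos(order: int, cutoff_hz: float, fs: float) -> np.ndarray:
    """Digital low-pass Bessel (bilinear transform, -3 dB at cutoff), unity DC."""
    if cutoff_hz >= fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz:g} Hz must be below the Nyquist rate {fs / 2:g} Hz"
        )
    sos = signal.bessel(order, cutoff_hz, btype="low", output="sos",
                        fs=fs, norm="mag")
    # Force DC gain to exactly 1 (bilinear design is within rounding already).
    w, h = signal.sosfreqz(sos, worN=[0.0], fs=fs)
    sos = sos.copy()
    sos[0, :3] /= abs(h[0])
    return sos


def _sosfilt_causal(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    # Initialize internal state to steady state at the first sample so the
    # record does not start with an artificial step from zero.
    zi = signal.sosfilt_zi(sos) * x[0]
    y, _ = signal.sosfilt(sos, x, zi=zi)
    return y


def apply_filter(trace: Trace, spec: FilterSpec) -> Trace:
    """Apply one filter stage; the returned trace's metadata records it."""
    if spec.kind == "bessel_lowpass":
        if spec.cutoff_hz is None:
            raise ValueError("bessel_lowpass requires cutoff_hz")
        sos = bessel_sos(spec.order, spec.cutoff_hz, trace.sample_rate_hz)
        y = _sosfilt_causal(sos, trace.i_pA)
        out = trace.with_current(y)
    elif spec.kind == "savitzky_golay":
        if spec.window_s is None:
            raise ValueError("savitzky_golay requires window_s")
        out = _savgol(trace, spec.window_s)
    elif spec.kind == "decimate":
        if not spec.factor or spec.factor < 1:
            raise ValueError("decimate requires a positive integer factor")
        return decimate(trace, spec.factor)
    else:
        raise ValueError(f"unknown filter kind {spec.kind!r}")
    out.metadata["filters"].append(spec.describe())
    return out


def bessel_lowpass(trace: Trace, cutoff_hz: float, order: int = 4) -> Trace:
    return apply_filter(trace, FilterSpec("bessel_lowpass", cutoff_hz=cutoff_hz,
                                          order=order))


def _savgol(trace: Trace, window_s: float) -> Trace:
    n = len(trace)
    win = int(round(window_s * trace.sample_rate_hz))
    win = max(win | 1, 3)  # odd, at least 3 samples
    if win >= n:
        raise ValueError(
            f"smoothing window ({win} samples) must be shorter than the trace ({n})"
        )
    y = signal.savgol_filter(trace.i_pA, win, polyorder=1, mode="interp")
    return trace.with_current(y)


def moving_average_sg(trace: Trace, window_s: float = 0.4) -> Trace:
    """Savitzky-Golay moving average (order 1) over ``window_s`` seconds."""
    out = _savgol(trace, window_s)
    out.metadata["filters"].append(
        FilterSpec("savitzky_golay", window_s=window_s).describe()
    )
    return out


def decimate(trace: Trace, factor: int) -> Trace:
    """Anti-alias filter then down-sample by an integer factor."""
    factor = int(factor)
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    if factor == 1:
        return trace
    y = signal.decimate(trace.i_pA, factor, ftype="fir", zero_phase=True)
    out = Trace(
        t=trace.t[::factor][: len(y)],
        i_pA=y,
        sample_rate_hz=trace.sample_rate_hz / factor,
        metadata={**trace.metadata,
                  "filters": list(trace.metadata.get("filters", []))},
        protocol=trace.protocol,
    )
    out.metadata["filters"].append(FilterSpec("decimate", factor=factor).describe())
    return out


def filter_chain(trace: Trace, specs: Sequence[FilterSpec]) -> Trace:
    for spec in specs:
        trace = apply_filter(trace, spec)
    return trace


def standard_chain(trace: Trace, digital_cutoff_hz: float = 20.0) -> Trace:
    """The standard recording chain: 5 kHz 4-pole Bessel then a digital low-pass
    Bessel at ``digital_cutoff_hz`` (skipping the 5 kHz stage when the trace
    is sampled too slowly to host it)."""
    fs = trace.sample_rate_hz
    if fs / 2 > 5000.0:
        trace = bessel_lowpass(trace, 5000.0)
    return bessel_lowpass(trace, digital_cutoff_hz)


def noise_bandwidth_fraction(cutoff_hz: float, order: int, fs: float,
                             n_freq: int = 4096) -> float:
    """Fraction of white-noise variance passed by the digital Bessel filter.

    Computed numerically as the mean of |H(f)|^2 over 0..Nyquist, so a raw
    trace with s.d. sigma filters to s.d. sigma * sqrt(fraction).
    """
    sos = bessel_sos(order, cutoff_hz, fs)
    w, h = signal.sosfreqz(sos, worN=n_freq, fs=fs)
    return float(np.trapezoid(np.abs(h) ** 2, w) / (fs / 2))
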