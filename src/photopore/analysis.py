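"""Summary statistics and trace-analysis procedures for photopore recordings.

Core quantities:

* per cent gated current, ``I_gate% = (1 - I_OFF/I_ON) * 100`` — the
  fractional current blocked between the ON and OFF photostationary states;
* its fold-change equivalent ``1 / (1 - I_gate%/100)`` (95% gating = 20-fold
  conductance increase);
* the rectification ratio ``|I(-V)| / |I(+V)|`` of the diode state;
* I-V extraction from staircase-ramp recordings;
* response times of light-driven transitions;
* changepoint (step) detection on single-pore traces, where each stepwise
  current change reflects isomerization of one or more switches;
* the level-capacity estimate range/fluctuation for amplitude encoding.

Level estimators: ensembles average over the pore population, so the
equilibrium level is the mean over an equilibrium window (default the last
20% of a light segment).  A single pore at a photostationary state dwells
mostly in the extreme configuration and makes excursions to neighbours, so
its ON/OFF levels are read from the extreme sustained plateau (rolling-mean
extremum) rather than the window mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, optimize

from .filters import moving_average_sg
from .simulate import Protocol, StepVoltage, Trace

__all__ = [
    "GatingResult",
    "IVCurve",
    "LevelCapacity",
    "gating_percent",
    "fold_change_from_gating",
    "rectification_ratio",
    "extract_iv",
    "response_time",
    "detect_steps",
    "level_capacity",
    "estimate_pz_from_ensemble",
    "segment_window",
    "window_mean",
    "plateau_extreme_level",
    "gating_from_trace",
    "half_cycle_rectification",
]


# ---------------------------------------------------------------------------
# Scalar statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GatingResult:
    i_on_pA: float
    i_off_pA: float
    n_replicates: int = 1

    @property
    def i_gate_percent(self) -> float:
        return gating_percent(self.i_on_pA, self.i_off_pA)

    @property
    def fold_change(self) -> float:
        return fold_change_from_gating(self.i_gate_percent)


def gating_percent(i_on: float, i_off: float) -> float:
    """Per cent gated current (1 - I_OFF/I_ON) * 100."""
    if i_on == 0:
        raise ValueError("I_ON must be nonzero")
    return (1.0 - i_off / i_on) * 100.0


def fold_change_from_gating(i_gate_percent: float) -> float:
    """Conductance fold change implied by a gating percentage (95% -> 20x)."""
    if i_gate_percent >= 100.0:
        return math.inf
    return 1.0 / (1.0 - i_gate_percent / 100.0)


class LevelCapacity(NamedTuple):
    raw: float
    rounded: float  # one significant figure


def level_capacity(range_percent: float, fluctuation_percent: float) -> LevelCapacity:
    """Upper estimate of assignable current levels: range / fluctuation.

    With the full gating range ~0-85% and dark fluctuations of +/-0.3% after
    20 Hz filtering, roughly 300 levels are distinguishable in principle.
    The rounded value is reported to one significant figure.
    """
    if range_percent <= 0 or fluctuation_percent <= 0:
        raise ValueError("range and fluctuation must be positive")
    raw = range_percent / fluctuation_percent
    exponent = math.floor(math.log10(raw))
    rounded = round(raw / 10**exponent) * 10**exponent
    return LevelCapacity(raw, float(rounded))


def estimate_pz_from_ensemble(
    i_eq: float, i_on: float, i_off: float
) -> Tuple[float, bool]:
    """Invert the linear configuration map: Z fraction from an equilibrium
    current given the fully-ON and fully-OFF levels.  Returns (fraction,
    clipped) where ``clipped`` flags values outside [0, 1]."""
    if i_on == i_off:
        raise ValueError("degenerate levels: I_ON == I_OFF")
    p = (i_eq - i_off) / (i_on - i_off)
    clipped = not 0.0 <= p <= 1.0
    return float(np.clip(p, 0.0, 1.0)), clipped


# ---------------------------------------------------------------------------
# I-V curves
# ---------------------------------------------------------------------------

@dataclass
class IVCurve:
    voltage_mV: np.ndarray
    current_pA: np.ndarray
    ci95_pA: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if np.any(np.diff(self.voltage_mV) <= 0):
            raise ValueError("voltage grid must be strictly increasing")

    def current_at(self, v_mV: float) -> float:
        idx = np.nonzero(np.isclose(self.voltage_mV, v_mV, atol=1e-6))[0]
        if idx.size == 0:
            raise ValueError(f"no measurement at {v_mV} mV")
        return float(self.current_pA[idx[0]])

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.voltage_mV, self.current_pA]),
                   delimiter=",", header="voltage_mV,current_pA", comments="")


def extract_iv(trace: Trace, settle_fraction: float = 0.5) -> IVCurve:
    """I-V curve from a staircase (ramp) recording.

    For each holding step the current is averaged over the final
    ``1 - settle_fraction`` of the dwell (the settled portion); the 95%
    confidence half-width is estimated from the within-window spread.
    """
    proto = trace.protocol
    if proto is None or not isinstance(proto.voltage, StepVoltage):
        raise ValueError("trace does not carry a step/ramp voltage protocol")
    steps = proto.voltage
    edges = steps.edges
    fs = trace.sample_rate_hz
    v_list, i_list, ci_list = [], [], []
    for k, (dur, v) in enumerate(steps.steps):
        t0 = edges[k] + settle_fraction * dur
        t1 = edges[k + 1]
        lo, hi = int(math.ceil(t0 * fs)), int(t1 * fs)
        hi = min(hi, len(trace))
        if hi - lo < 2:
            raise ValueError("dwell too short for the sampling rate")
        win = trace.i_pA[lo:hi]
        v_list.append(v)
        i_list.append(win.mean())
        ci_list.append(1.96 * win.std(ddof=1) / math.sqrt(win.size))
    order = np.argsort(v_list)
    return IVCurve(np.asarray(v_list)[order], np.asarray(i_list)[order],
                   np.asarray(ci_list)[order])


def rectification_ratio(iv_or_trace, v_mV: float) -> float:
    """|I(-V)| / |I(+V)| from an I-V curve or a ramp-protocol trace."""
    if v_mV <= 0:
        raise ValueError("rectification ratio requires V > 0")
    iv = iv_or_trace if isinstance(iv_or_trace, IVCurve) else extract_iv(iv_or_trace)
    i_pos = iv.current_at(+v_mV)
    i_neg = iv.current_at(-v_mV)
    if i_pos == 0:
        return math.inf
    return abs(i_neg) / abs(i_pos)


# ---------------------------------------------------------------------------
# Response times
# ---------------------------------------------------------------------------

def response_time(
    trace: Trace,
    onset_s: float,
    from_level: float,
    to_level: float,
    threshold: float = 0.9,
    smooth_window_s: float = 0.2,
    method: str = "threshold",
) -> float:
    """Time from light onset until the smoothed current completes the
    transition.

    ``method='threshold'`` (default): first crossing of
    ``from_level + threshold * (to_level - from_level)`` after onset.
    ``method='expfit'``: fit an exponential relaxation after onset and report
    the time at which the fit reaches the same threshold
    (``tau * ln(1/(1-threshold))``).  Returns NaN if the transition is never
    reached.
    """
    if from_level == to_level:
        raise ValueError("from_level and to_level must differ")
    fs = trace.sample_rate_hz
    n_win = int(round(smooth_window_s * fs))
    x = trace.i_pA
    if n_win >= 3:
        x = ndimage.uniform_filter1d(x, n_win | 1, mode="nearest")
    i0 = int(round(onset_s * fs))
    if i0 >= len(x):
        raise ValueError("onset beyond end of trace")
    seg = x[i0:]
    tt = np.arange(seg.size) / fs

    if method == "expfit":
        span = to_level - from_level

        def model(t, tau):
            return to_level - span * np.exp(-t / tau)

        try:
            (tau,), _ = optimize.curve_fit(model, tt, seg, p0=[1.0],
                                           bounds=(1e-6, np.inf))
        except RuntimeError:
            return float("nan")
        return float(tau * math.log(1.0 / (1.0 - threshold)))

    target = from_level + threshold * (to_level - from_level)
    rising = to_level > from_level
    hits = np.nonzero(seg >= target if rising else seg <= target)[0]
    if hits.size == 0:
        return float("nan")
    return float(tt[hits[0]])


# ---------------------------------------------------------------------------
# Step detection (changepoints)
# ---------------------------------------------------------------------------

def _sse(prefix: np.ndarray, prefix2: np.ndarray, lo: int, hi: int) -> float:
    n = hi - lo
    s = prefix[hi] - prefix[lo]
    s2 = prefix2[hi] - prefix2[lo]
    return max(s2 - s * s / n, 0.0)


def detect_steps(
    trace: Trace,
    min_dwell_s: float = 0.05,
    min_amplitude: Optional[float] = None,
    smooth_window_s: float = 0.4,
    max_levels: int = 64,
) -> List[Tuple[float, float]]:
    """Piecewise-constant segmentation of a single-pore trace.

    Binary segmentation on the Savitzky-Golay-smoothed trace with a BIC
    stopping rule, a minimum dwell per level and a minimum step amplitude
    (default 6x a robust noise estimate).  Returns chronological
    ``(start_time_s, level_pA)`` pairs, the first entry being the initial
    level.  A monotone switching episode of one pore yields at most 7 steps
    (8 levels).
    """
    fs = trace.sample_rate_hz
    if int(round(smooth_window_s * fs)) >= 3 and len(trace) > int(
        round(smooth_window_s * fs) | 1
    ):
        x = moving_average_sg(trace, smooth_window_s).i_pA
    else:
        x = trace.i_pA.astype(float)
    n = x.size
    w = max(int(round(min_dwell_s * fs)), 2)

    # Robust noise scale from lagged differences of the smoothed trace.  The
    # lag must exceed the smoothing window so the two points are
    # decorrelated; the median keeps genuine steps out of the estimate.
    n_smooth = int(round(smooth_window_s * fs)) | 1
    lag = min(max(w // 2, n_smooth + 1, 1), max(n - 2, 1))
    d = x[lag:] - x[:-lag]
    sd = 1.4826 * np.median(np.abs(d - np.median(d))) / math.sqrt(2.0)
    if min_amplitude is None:
        min_amplitude = 6.0 * max(sd, 1e-12)

    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix2 = np.concatenate([[0.0], np.cumsum(x * x)])
    eps = 1e-12 * max(float(np.abs(x).max()), 1.0) ** 2 * n

    breakpoints: List[int] = []

    def split(lo: int, hi: int, depth: int) -> None:
        if hi - lo < 2 * w or depth > max_levels:
            return
        sse0 = _sse(prefix, prefix2, lo, hi)
        ks = np.arange(lo + w, hi - w + 1)
        if ks.size == 0:
            return
        nl = ks - lo
        nr = hi - ks
        sl = prefix[ks] - prefix[lo]
        sr = prefix[hi] - prefix[ks]
        s2l = prefix2[ks] - prefix2[lo]
        s2r = prefix2[hi] - prefix2[ks]
        sse_lr = (s2l - sl * sl / nl) + (s2r - sr * sr / nr)
        k_best = int(ks[np.argmin(sse_lr)])
        sse1 = float(sse_lr.min())
        m = hi - lo
        # BIC: a changepoint adds 2 parameters (location + level).
        bic_gain = m * math.log((sse1 + eps) / (sse0 + eps)) + 2.0 * math.log(n)
        amp = abs(
            (prefix[k_best] - prefix[lo]) / (k_best - lo)
            - (prefix[hi] - prefix[k_best]) / (hi - k_best)
        )
        if bic_gain >= 0.0 or amp < min_amplitude:
            return
        breakpoints.append(k_best)
        split(lo, k_best, depth + 1)
        split(k_best, hi, depth + 1)

    split(0, n, 0)
    bps = sorted(breakpoints)
    bounds = [0] + bps + [n]
    out: List[Tuple[float, float]] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        level = float((prefix[hi] - prefix[lo]) / (hi - lo))
        out.append((trace.t[lo], level))
    return out


# ---------------------------------------------------------------------------
# Segment-level estimation and gating from traces
# ---------------------------------------------------------------------------

def segment_window(seg, window_fraction: float = 0.2) -> Tuple[float, float]:
    """Equilibrium window: the final ``window_fraction`` of a light segment."""
    t1 = seg.end_s
    return t1 - window_fraction * seg.duration_s, t1


def window_mean(trace: Trace, t0: float, t1: float) -> float:
    fs = trace.sample_rate_hz
    lo, hi = int(math.ceil(t0 * fs)), min(int(t1 * fs), len(trace))
    if hi - lo < 1:
        raise ValueError("empty analysis window")
    return float(trace.i_pA[lo:hi].mean())


def plateau_extreme_level(
    trace: Trace, t0: float, t1: float, side: str, window_s: float = 1.0
) -> float:
    """Extreme sustained level within [t0, t1]: min/max of a rolling mean.

    Reads the deepest (or highest) plateau the pore visits — for a single
    pore at a photostationary state this is the fully-OFF (or fully-ON)
    level, visited repeatedly even though neighbouring configurations are
    also populated.
    """
    fs = trace.sample_rate_hz
    lo, hi = int(math.ceil(t0 * fs)), min(int(t1 * fs), len(trace))
    x = trace.i_pA[lo:hi]
    n_win = max(int(round(window_s * fs)) | 1, 1)
    if x.size < n_win + 2:
        raise ValueError("window too short for plateau estimation")
    r = ndimage.uniform_filter1d(x, n_win, mode="nearest")
    half = n_win // 2
    r = r[half: x.size - half] if x.size > 2 * half else r
    return float(r.min() if side == "min" else r.max())


def _segments_at(protocol: Protocol, wavelength_nm: int):
    segs = [
        s for s in protocol.light_segments
        if any(w == wavelength_nm for w, q in s.field.sources if q > 0)
        and len([1 for w, q in s.field.sources if q > 0]) == 1
    ]
    if not segs:
        raise ValueError(f"protocol has no {wavelength_nm} nm segments")
    return segs


def gating_from_trace(
    trace: Trace,
    on_nm: int = 365,
    off_nm: int = 530,
    window_fraction: Optional[float] = None,
    estimator: str = "mean",
    plateau_window_s: float = 1.0,
) -> GatingResult:
    """I_gate% from a trace cycling between the ON and OFF wavelengths.

    ``estimator='mean'`` (ensembles): equilibrium-window means over the last
    20% of each light segment.
    ``estimator='plateau'`` (single pores): extreme sustained plateau within
    the settled half of each segment — the fully-ON / fully-OFF levels.
    The window is wider here because the pore must *visit* the extreme
    configuration (dwells at the fully-OFF state last tens of seconds under
    green light).
    """
    if trace.protocol is None:
        raise ValueError("trace carries no protocol metadata")
    if window_fraction is None:
        window_fraction = 0.2 if estimator == "mean" else 0.5
    on_segs = _segments_at(trace.protocol, on_nm)
    off_segs = _segments_at(trace.protocol, off_nm)

    def level(seg, side: str) -> float:
        t0, t1 = segment_window(seg, window_fraction)
        if estimator == "mean":
            return window_mean(trace, t0, t1)
        if estimator == "plateau":
            return plateau_extreme_level(trace, t0, t1, side,
                                         window_s=plateau_window_s)
        raise ValueError(f"unknown estimator {estimator!r}")

    on_levels = [level(s, "max") for s in on_segs]
    off_levels = [level(s, "min") for s in off_segs]
    if estimator == "plateau":
        # One fully-ON / fully-OFF level per recording: the extreme over all
        # segments (a single segment may not visit the extreme configuration).
        i_on, i_off = float(np.max(on_levels)), float(np.min(off_levels))
    else:
        i_on, i_off = float(np.mean(on_levels)), float(np.mean(off_levels))
    return GatingResult(i_on, i_off, n_replicates=min(len(on_segs), len(off_segs)))


def half_cycle_rectification(trace: Trace, resistive_only: bool = False) -> float:
    """Half-wave rectification metric for a sinusoidal-voltage trace:
    mean |I| over negative-potential samples / mean |I| over positive ones.

    With ``resistive_only`` the bilayer capacitive current (known
    analytically from the waveform and the recorded capacitance) is
    subtracted first.
    """
    proto = trace.protocol
    if proto is None:
        raise ValueError("trace carries no protocol metadata")
    v = proto.voltage.voltage(trace.t) + proto.emf_offset_mV
    i = trace.i_pA
    if resistive_only:
        cap_pF = trace.metadata.get("capacitance_pF")
        if cap_pF is not None:
            i = i - cap_pF * proto.voltage.dvdt(trace.t) * 1e-3
    neg = v < 0
    pos = v > 0
    if not neg.any() or not pos.any():
        raise ValueError("trace does not cover both polarities")
    denom = float(np.abs(i[pos]).mean())
    if denom == 0:
        return math.inf
    return float(np.abs(i[neg]).mean()) / denom
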