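"""Synthetic voltage-clamp recordings of photopore ensembles.

Each of the 7 photoswitches of each pore evolves as an independent two-state
continuous-time Markov chain whose E->Z / Z->E rates are piecewise-constant
in time, set by the irradiation protocol through
:func:`photopore.photochemistry.effective_rates`.  Switching is simulated
exactly (event-driven, exponential waiting times redrawn at every protocol
segment boundary); the total membrane current is rendered on a uniform
sampling grid as

    I(t) = sum_p s_p * [ i_off(V(t)) + f_p(t) * (i_on(V(t)) - i_off(V(t))) ]
           + C * dV/dt + noise + drift,

where f_p = n_Z/7 is the pore's ON weight, s_p an optional per-pore
conductance scale, and the capacitive term applies to smooth (sinusoidal)
waveforms — step changes are treated as compensated by the amplifier.

Recording noise is additive white Gaussian.  Its standard deviation is
specified at the output of the 20 Hz digital Bessel filter (default 0.3% of
the fully-ON full-scale current, the dark-trace fluctuation of the recording
chain); the raw-trace s.d. is back-computed from that filter's equivalent
noise bandwidth so that the filtered trace lands on the specified level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .photochemistry import (
    DARK,
    LightField,
    PhotoswitchParams,
    effective_rates,
    preset,
    pss_fraction_Z,
    relax_fraction_Z,
)
from .pores import ConductanceModel, N_SUBUNITS, sample_pore_conductances

__all__ = [
    "ConstantVoltage",
    "StepVoltage",
    "RampVoltage",
    "SineVoltage",
    "LightSegment",
    "Protocol",
    "Trace",
    "EnsembleModel",
    "SwitchingEvents",
    "simulate_switching",
    "simulate",
    "state_census",
    "ac_response",
    "DEFAULT_SAMPLE_RATE",
]

DEFAULT_SAMPLE_RATE = 25_000.0  # Hz, the recording digitization rate


# ---------------------------------------------------------------------------
# Voltage waveforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstantVoltage:
    v_mV: float = 100.0

    def voltage(self, t) -> np.ndarray:
        return np.full_like(np.asarray(t, dtype=float), self.v_mV)

    def dvdt(self, t) -> np.ndarray:
        return np.zeros_like(np.asarray(t, dtype=float))

    def to_dict(self) -> dict:
        return {"kind": "constant", "v_mV": self.v_mV}


@dataclass(frozen=True)
class StepVoltage:
    """A sequence of (duration_s, v_mV) holding levels; held at the last level."""

    steps: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        st = tuple((float(d), float(v)) for d, v in self.steps)
        if not st or any(d <= 0 for d, _ in st):
            raise ValueError("steps must be non-empty with positive durations")
        object.__setattr__(self, "steps", st)

    @property
    def edges(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([d for d, _ in self.steps])])

    @property
    def levels(self) -> np.ndarray:
        return np.array([v for _, v in self.steps])

    def voltage(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.edges, t, side="right") - 1,
                      0, len(self.steps) - 1)
        return self.levels[idx]

    def dvdt(self, t) -> np.ndarray:
        # Step transients treated as capacitance-compensated.
        return np.zeros_like(np.asarray(t, dtype=float))

    def to_dict(self) -> dict:
        return {"kind": "steps", "steps": [list(s) for s in self.steps]}


def RampVoltage(
    v_start_mV: float = -200.0,
    v_stop_mV: float = 200.0,
    step_mV: float = 10.0,
    dwell_s: float = 0.5,
) -> StepVoltage:
    """Staircase ramp (default -200 to +200 mV in 10 mV steps)."""
    n = int(round((v_stop_mV - v_start_mV) / step_mV)) + 1
    levels = v_start_mV + step_mV * np.arange(n)
    return StepVoltage(tuple((dwell_s, float(v)) for v in levels))


@dataclass(frozen=True)
class SineVoltage:
    amplitude_mV: float
    frequency_Hz: float
    offset_mV: float = 0.0

    def voltage(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.offset_mV + self.amplitude_mV * np.sin(
            2.0 * np.pi * self.frequency_Hz * t
        )

    def dvdt(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        w = 2.0 * np.pi * self.frequency_Hz
        return self.amplitude_mV * w * np.cos(w * t)

    def to_dict(self) -> dict:
        return {"kind": "sine", "amplitude_mV": self.amplitude_mV,
                "frequency_Hz": self.frequency_Hz, "offset_mV": self.offset_mV}


Waveform = Union[ConstantVoltage, StepVoltage, SineVoltage]


def waveform_from_dict(d: dict) -> Waveform:
    kind = d.get("kind", "constant")
    if kind == "constant":
        return ConstantVoltage(float(d.get("v_mV", 100.0)))
    if kind == "steps":
        return StepVoltage(tuple((float(a), float(b)) for a, b in d["steps"]))
    if kind == "ramp":
        return RampVoltage(
            float(d.get("v_start_mV", -200.0)), float(d.get("v_stop_mV", 200.0)),
            float(d.get("step_mV", 10.0)), float(d.get("dwell_s", 0.5)),
        )
    if kind == "sine":
        return SineVoltage(
            float(d["amplitude_mV"]), float(d["frequency_Hz"]),
            float(d.get("offset_mV", 0.0)),
        )
    raise ValueError(f"unknown waveform kind {kind!r}")


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LightSegment:
    start_s: float
    duration_s: float
    field: LightField

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.start_s < 0:
            raise ValueError("light segment must have start >= 0 and duration > 0")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class Protocol:
    """Time-aligned irradiation segments plus a voltage waveform.

    Gaps between light segments are dark.  ``emf_offset_mV`` is a constant
    electrochemical driving force added to the applied potential (e.g. the
    Nernst potential of an asymmetric KCl gradient, ~59 mV per decade).
    """

    duration_s: float
    light_segments: Tuple[LightSegment, ...] = ()
    voltage: Waveform = field(default_factory=ConstantVoltage)
    emf_offset_mV: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("protocol duration must be positive")
        segs = tuple(sorted(self.light_segments, key=lambda s: s.start_s))
        last_end = 0.0
        for s in segs:
            if s.start_s < last_end - 1e-12:
                raise ValueError("light segments overlap")
            if s.end_s > self.duration_s + 1e-9:
                raise ValueError("light segment extends beyond protocol duration")
            last_end = s.end_s
        object.__setattr__(self, "light_segments", segs)

    def intervals(self) -> List[Tuple[float, float, LightField]]:
        """Maximal intervals of constant light, covering [0, duration]."""
        out: List[Tuple[float, float, LightField]] = []
        t = 0.0
        for s in self.light_segments:
            if s.start_s > t:
                out.append((t, s.start_s, DARK))
            out.append((s.start_s, s.end_s, s.field))
            t = s.end_s
        if t < self.duration_s:
            out.append((t, self.duration_s, DARK))
        return out

    @classmethod
    def light_cycle(
        cls,
        fields_and_durations: Sequence[Tuple[LightField, float]],
        voltage: Waveform | float = 100.0,
        emf_offset_mV: float = 0.0,
    ) -> "Protocol":
        """Concatenate light phases back-to-back (use DARK for dark phases)."""
        if isinstance(voltage, (int, float)):
            voltage = ConstantVoltage(float(voltage))
        segs, t = [], 0.0
        for fld, dur in fields_and_durations:
            if not fld.is_dark:
                segs.append(LightSegment(t, dur, fld))
            t += dur
        return cls(duration_s=t, light_segments=tuple(segs), voltage=voltage,
                   emf_offset_mV=emf_offset_mV)

    def to_dict(self) -> dict:
        return {
            "duration_s": self.duration_s,
            "light_segments": [
                {"start_s": s.start_s, "duration_s": s.duration_s,
                 "field": s.field.to_dict()}
                for s in self.light_segments
            ],
            "voltage": self.voltage.to_dict(),
            "emf_offset_mV": self.emf_offset_mV,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls(
            duration_s=float(d["duration_s"]),
            light_segments=tuple(
                LightSegment(float(s["start_s"]), float(s["duration_s"]),
                             LightField.from_dict(s["field"]))
                for s in d.get("light_segments", [])
            ),
            voltage=waveform_from_dict(d.get("voltage", {"kind": "constant"})),
            emf_offset_mV=float(d.get("emf_offset_mV", 0.0)),
        )


# ---------------------------------------------------------------------------
# Traces and the ensemble model
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """A uniformly sampled current record with provenance metadata."""

    t: np.ndarray
    i_pA: np.ndarray
    sample_rate_hz: float
    metadata: dict = field(default_factory=dict)
    protocol: Optional[Protocol] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.i_pA = np.asarray(self.i_pA, dtype=float)
        if self.t.shape != self.i_pA.shape:
            raise ValueError("time and current arrays must have the same shape")
        self.metadata.setdefault("filters", [])

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return len(self.t) / self.sample_rate_hz

    def with_current(self, i_pA: np.ndarray, extra_meta: dict | None = None) -> "Trace":
        meta = {**self.metadata, "filters": list(self.metadata.get("filters", []))}
        if extra_meta:
            meta.update(extra_meta)
        return Trace(self.t.copy(), np.asarray(i_pA, dtype=float),
                     self.sample_rate_hz, meta, self.protocol)


@dataclass(frozen=True)
class EnsembleModel:
    """A bilayer carrying ``n_pores`` photopores plus the recording chain.

    ``pore_scales`` holds per-pore conductance scale factors (pore ON
    conductance / model ``g_on_nS``); ``None`` means identical pores.
    ``noise_fraction`` is the Gaussian current s.d. after 20 Hz filtering,
    as a fraction of the fully-ON ensemble current.
    """

    n_pores: int = 1
    conductance: ConductanceModel = field(default_factory=ConductanceModel)
    photoswitch: PhotoswitchParams = field(default_factory=preset)
    pore_scales: Optional[np.ndarray] = None
    capacitance_pF: float = 100.0
    noise_fraction: float = 0.003
    drift_pA_per_s: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pores < 1:
            raise ValueError("n_pores must be >= 1")
        if self.noise_fraction < 0:
            raise ValueError("noise fraction must be >= 0")
        if self.pore_scales is not None:
            sc = np.asarray(self.pore_scales, dtype=float)
            if sc.shape != (self.n_pores,):
                raise ValueError("pore_scales must have one entry per pore")
            object.__setattr__(self, "pore_scales", sc)

    @classmethod
    def with_sampled_pores(
        cls, n_pores: int, seed, heterogeneity: bool = True, **kwargs
    ) -> "EnsembleModel":
        """Build an ensemble with per-pore ON conductances drawn from the
        truncated-normal heterogeneity distribution (reproducible by seed)."""
        cond = kwargs.pop("conductance", ConductanceModel())
        scales = None
        if heterogeneity:
            rng = np.random.default_rng(seed)
            g = sample_pore_conductances(cond, n_pores, rng)
            scales = g / cond.g_on_nS
        return cls(n_pores=n_pores, conductance=cond, pore_scales=scales, **kwargs)

    @property
    def scales(self) -> np.ndarray:
        if self.pore_scales is None:
            return np.ones(self.n_pores)
        return self.pore_scales

    @property
    def i_full_scale_pA(self) -> float:
        return float(self.scales.sum() * self.conductance.i_full_scale_pA)


# ---------------------------------------------------------------------------
# Event-driven switching
# ---------------------------------------------------------------------------

@dataclass
class SwitchingEvents:
    """Exact isomerization event record for an ensemble simulation."""

    n_pores: int
    n_Z0: np.ndarray          # initial n_Z per pore
    times: np.ndarray         # event times, sorted ascending
    pore_index: np.ndarray    # which pore flipped
    delta_n_Z: np.ndarray     # +1 (E->Z) or -1 (Z->E)
    final_states: np.ndarray  # (n_pores, 7) boolean, True = Z

    def n_Z_trajectory(self, pore: int) -> Tuple[np.ndarray, np.ndarray]:
        """(event times, n_Z after each event) for one pore, starting level
        prepended at t=0."""
        mask = self.pore_index == pore
        tt = np.concatenate([[0.0], self.times[mask]])
        nz = self.n_Z0[pore] + np.concatenate(
            [[0], np.cumsum(self.delta_n_Z[mask])]
        )
        return tt, nz

    @property
    def final_n_Z(self) -> np.ndarray:
        return self.final_states.sum(axis=1)


def _initial_states(
    model: EnsembleModel,
    initial_state,
    rng: np.random.Generator,
) -> np.ndarray:
    n = model.n_pores
    if isinstance(initial_state, str):
        s = initial_state.upper()
        if s == "E":
            return np.zeros((n, N_SUBUNITS), dtype=bool)
        if s == "Z":
            return np.ones((n, N_SUBUNITS), dtype=bool)
        raise ValueError(f"unknown initial state {initial_state!r}")
    if np.isscalar(initial_state):
        p = float(initial_state)
        if not 0.0 <= p <= 1.0:
            raise ValueError("initial Z probability must be in [0, 1]")
        return rng.random((n, N_SUBUNITS)) < p
    arr = np.asarray(initial_state, dtype=bool)
    if arr.shape != (n, N_SUBUNITS):
        raise ValueError("initial state array must be (n_pores, 7)")
    return arr.copy()


def simulate_switching(
    model: EnsembleModel,
    protocol: Protocol,
    seed,
    initial_state="E",
) -> SwitchingEvents:
    """Exact (Gillespie) simulation of all switch flips under a protocol.

    Within each constant-light interval every switch's waiting time is
    exponential with the state-dependent leaving rate; waiting times are
    redrawn at each interval boundary (memorylessness makes this exact for
    piecewise-constant rates).
    """
    rng = np.random.default_rng(seed)
    states = _initial_states(model, initial_state, rng)  # True = Z
    n_Z0 = states.sum(axis=1).astype(int)
    flat = states.reshape(-1)
    n_sw = flat.size
    pore_of = np.repeat(np.arange(model.n_pores), N_SUBUNITS)

    ev_t: List[np.ndarray] = []
    ev_p: List[np.ndarray] = []
    ev_d: List[np.ndarray] = []

    for t0, t1, fld in protocol.intervals():
        k_ez, k_ze = effective_rates(model.photoswitch, fld)
        if k_ez == 0.0 and k_ze == 0.0:
            continue
        t_cur = np.full(n_sw, t0)
        active = np.ones(n_sw, dtype=bool)
        while True:
            idx = np.nonzero(active)[0]
            if idx.size == 0:
                break
            rates = np.where(flat[idx], k_ze, k_ez)
            dt = np.full(idx.size, np.inf)
            pos = rates > 0
            dt[pos] = rng.exponential(1.0 / rates[pos])
            t_next = t_cur[idx] + dt
            fire = t_next < t1
            fidx = idx[fire]
            if fidx.size == 0:
                break
            was_z = flat[fidx].copy()
            flat[fidx] = ~was_z
            t_cur[fidx] = t_next[fire]
            active[idx[~fire]] = False
            ev_t.append(t_next[fire])
            ev_p.append(pore_of[fidx])
            ev_d.append(np.where(was_z, -1, 1))

    if ev_t:
        times = np.concatenate(ev_t)
        order = np.argsort(times, kind="stable")
        times = times[order]
        pore_index = np.concatenate(ev_p)[order]
        delta = np.concatenate(ev_d)[order]
    else:
        times = np.empty(0)
        pore_index = np.empty(0, dtype=int)
        delta = np.empty(0, dtype=int)

    return SwitchingEvents(
        n_pores=model.n_pores,
        n_Z0=n_Z0,
        times=times,
        pore_index=pore_index,
        delta_n_Z=delta,
        final_states=flat.reshape(model.n_pores, N_SUBUNITS),
    )


# ---------------------------------------------------------------------------
# Trace rendering
# ---------------------------------------------------------------------------

def simulate(
    model: EnsembleModel,
    protocol: Protocol,
    seed,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    initial_state="E",
    return_states: bool = False,
):
    """Simulate a full recording: switching + conduction + noise + drift.

    Returns a :class:`Trace` (and the :class:`SwitchingEvents` when
    ``return_states`` is true).  All randomness derives from ``seed``; the
    same seed and inputs give a bit-identical trace.
    """
    rng = np.random.default_rng(np.random.SeedSequence([_seed_int(seed), 1]))
    events = simulate_switching(model, protocol, np.random.SeedSequence(
        [_seed_int(seed), 0]), initial_state=initial_state)

    n = int(round(protocol.duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    cond = model.conductance
    scales = model.scales

    # ON-branch weight A(t) = sum_p s_p * n_Z,p / 7, piecewise constant.
    a0 = float((scales * events.n_Z0).sum() / N_SUBUNITS)
    if events.times.size:
        da = events.delta_n_Z * scales[events.pore_index] / N_SUBUNITS
        cum_a = a0 + np.concatenate([[0.0], np.cumsum(da)])
        a_t = cum_a[np.searchsorted(events.times, t, side="right")]
    else:
        a_t = np.full(n, a0)

    v_t = protocol.voltage.voltage(t) + protocol.emf_offset_mV
    s_tot = float(scales.sum())
    i_off = cond.i_off(v_t)
    i_on = cond.i_on(v_t)
    current = s_tot * i_off + a_t * (i_on - i_off)

    # Bilayer capacitive current: C dV/dt of the applied waveform (pF * mV/s
    # * 1e-3 = pA); step edges are treated as amplifier-compensated.
    current = current + model.capacitance_pF * protocol.voltage.dvdt(t) * 1e-3

    if model.noise_fraction > 0:
        from .filters import noise_bandwidth_fraction

        sd_post = model.noise_fraction * model.i_full_scale_pA
        sd_raw = sd_post / np.sqrt(noise_bandwidth_fraction(20.0, 4, sample_rate))
        current = current + rng.normal(0.0, sd_raw, size=n)
    if model.drift_pA_per_s != 0.0:
        current = current + model.drift_pA_per_s * t

    trace = Trace(
        t=t,
        i_pA=current,
        sample_rate_hz=sample_rate,
        metadata={
            "filters": [],
            "n_pores": model.n_pores,
            "seed": _seed_int(seed),
            "noise_fraction": model.noise_fraction,
            "capacitance_pF": model.capacitance_pF,
            "i_full_scale_pA": model.i_full_scale_pA,
            "protocol": protocol.to_dict(),
        },
        protocol=protocol,
    )
    if return_states:
        return trace, events
    return trace


def _seed_int(seed) -> int:
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0]) % (2**31)
    return int(seed) % (2**31)


# ---------------------------------------------------------------------------
# Equilibrium census and AC response
# ---------------------------------------------------------------------------

def state_census(
    model: EnsembleModel,
    light: LightField,
    t_s: float = np.inf,
    seed=0,
    initial_p_Z: float = 0.0,
) -> np.ndarray:
    """Sampled counts of pores at each n_Z (length-8 array) at time ``t_s``.

    Switches are i.i.d., so at any time the pore composition is
    Binomial(7, p_Z(t)); at equilibrium p_Z is the photostationary fraction.
    """
    if np.isinf(t_s):
        p = pss_fraction_Z(model.photoswitch, light)
    else:
        p = relax_fraction_Z(model.photoswitch, light, initial_p_Z, t_s)
    rng = np.random.default_rng(seed)
    n_z = rng.binomial(N_SUBUNITS, p, size=model.n_pores)
    return np.bincount(n_z, minlength=N_SUBUNITS + 1)


def ac_response(
    model: EnsembleModel,
    amplitude_mV: float,
    frequency_Hz: float,
    state: str = "off",
    n_cycles: float = 3.0,
    seed=0,
    sample_rate: float = 1000.0,
) -> Trace:
    """Current under a sinusoidal potential with the pores held ON or OFF.

    The configuration is frozen (dark protocol; the arylazopyrazole does not
    thermally relax), isolating the diode's half-wave rectification and the
    bilayer's capacitive current.  Raising the frequency raises C*dV/dt and
    degrades the rectification of the total current.
    """
    dur = n_cycles / frequency_Hz
    proto = Protocol(
        duration_s=dur,
        voltage=SineVoltage(amplitude_mV, frequency_Hz),
    )
    init = "Z" if state.lower() == "on" else "E"
    return simulate(model, proto, seed, sample_rate=sample_rate,
                    initial_state=init)
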