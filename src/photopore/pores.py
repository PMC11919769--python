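"""Configuration-dependent conductance of a heptameric photopore.

A pore carries 7 photoswitches, one per subunit, each in the *E* or *Z*
isomer.  A pore state is summarized by (n_E, n_Z) with n_E + n_Z = 7; the
fully-Z pore (0E, 7Z) is the high-conductance ON state and the fully-E pore
(7E, 0Z) the low-leak OFF state.  Distinct rotational arrangements of the
same (n_E, n_Z) composition around the 7-fold pore axis are counted as binary
necklaces (cyclic group C7, no reflections).

The current-voltage behaviour is two-branched:

* ON branch — near-ohmic "photoresistor": slope ``g_on`` at positive
  potentials with a mild asymmetry factor at negative potentials
  (0.58/0.46 from the measured single-pore slopes).
* OFF branch — iontronic diode: ohmic conduction at negative potentials
  (0.32 nS), and at positive potentials a small saturating leak anchored at
  ``g_off_fraction`` of the ON current at +100 mV.  The saturating shape
  makes the rectification ratio |I(-V)|/|I(+V)| grow roughly linearly with V,
  as observed up to +/-150 mV.

Mixed configurations interpolate linearly between the two branch currents
with weight n_Z/7 (the default configuration->conductance map).  Sign
convention: positive current is cation flow from the *trans* to the *cis*
side at positive trans-side potential.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "N_SUBUNITS",
    "PoreConfiguration",
    "TruncatedNormalSpec",
    "ConductanceModel",
    "count_arrangements",
    "pore_current",
    "rectification_ratio_model",
    "sample_pore_conductances",
    "nand_truth_table",
    "iv_curve_points",
]

N_SUBUNITS = 7


# ---------------------------------------------------------------------------
# Configurations and rotational combinatorics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoreConfiguration:
    """The ordered (around the pore axis) E/Z states of the 7 switches."""

    states: Tuple[str, ...]

    def __post_init__(self) -> None:
        st = tuple(s.upper() for s in self.states)
        if len(st) != N_SUBUNITS or any(s not in ("E", "Z") for s in st):
            raise ValueError("states must be a 7-tuple of 'E'/'Z'")
        object.__setattr__(self, "states", st)

    @classmethod
    def from_n_Z(cls, n_Z: int) -> "PoreConfiguration":
        if not 0 <= n_Z <= N_SUBUNITS:
            raise ValueError(f"n_Z must be in 0..7, got {n_Z}")
        return cls(tuple(["Z"] * n_Z + ["E"] * (N_SUBUNITS - n_Z)))

    @property
    def n_Z(self) -> int:
        return sum(s == "Z" for s in self.states)

    @property
    def n_E(self) -> int:
        return N_SUBUNITS - self.n_Z

    @property
    def arrangement_class(self) -> Tuple[str, ...]:
        """Lexicographically minimal rotation: canonical necklace representative."""
        rotations = [
            self.states[i:] + self.states[:i] for i in range(N_SUBUNITS)
        ]
        return min(rotations)

    def __str__(self) -> str:  # e.g. "(5E, 2Z)"
        return f"({self.n_E}E, {self.n_Z}Z)"


def count_arrangements(n_Z: int, n: int = N_SUBUNITS) -> int:
    """Number of rotation-distinct arrangements of ``n_Z`` Z switches among ``n``.

    Binary necklaces of length ``n`` with exactly ``n_Z`` ones under the cyclic
    rotation group (Burnside's lemma; no reflections).  For the heptamer,
    e.g. two Z switches among seven subunits can sit adjacent, one apart or
    two apart: three arrangements.
    """
    if not 0 <= n_Z <= n:
        raise ValueError(f"n_Z must be in 0..{n}, got {n_Z}")
    total = 0
    for g in range(n):
        d = math.gcd(g, n)  # rotation by g has d cycles of length n/d
        if n_Z % (n // d) == 0:
            total += math.comb(d, n_Z // (n // d))
    return total // n


# ---------------------------------------------------------------------------
# Conductance model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruncatedNormalSpec:
    """Truncated-normal spec for per-pore ON conductance heterogeneity (nS)."""

    mean: float = 0.62
    sd: float = 0.30
    lower: float = 0.12
    upper: float = 1.27

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("truncation bounds must satisfy lower < upper")
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def _frozen(self):
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    @property
    def analytic_mean(self) -> float:
        return float(self._frozen().mean())

    @property
    def analytic_sd(self) -> float:
        return float(self._frozen().std())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(n)
        return self._frozen().ppf(u)


@dataclass(frozen=True)
class ConductanceModel:
    """Branch I-V parameters and the configuration->conductance map.

    Parameters
    ----------
    g_on_nS:
        ON-branch slope at positive potentials; also the per-pore current
        normalization (+64 pA at +100 mV by the ensemble-counting convention).
    g_off_fraction:
        Fully-OFF positive-branch current as a fraction of the fully-ON
        current, 0.05 by calibration from the 95% single-channel gating.
    on_neg_ratio:
        ON-branch negative/positive slope ratio (weak rectification of the
        photoresistor state; 0.58/0.46 from the measured slopes).
    g_off_neg_nS:
        OFF-branch ohmic slope at negative potentials (the diode's conducting
        direction).
    rect_sat_mV:
        Shape scale of the saturating OFF-branch positive leak; smaller
        values make the rectification ratio grow more steeply with voltage.
    mode:
        "diode" (default, two-branch behaviour) or "resistor" (symmetric
        linear branches; useful for idealized checks).
    """

    g_on_nS: float = 0.64
    g_off_fraction: float = 0.05
    on_neg_ratio: float = 0.58 / 0.46
    g_off_neg_nS: float = 0.32
    rect_sat_mV: float = 30.0
    mode: str = "diode"
    interpolation: str = "linear"
    heterogeneity: TruncatedNormalSpec = field(default_factory=TruncatedNormalSpec)
    v_range_mV: float = 200.0

    def __post_init__(self) -> None:
        if not 0.0 < self.g_off_fraction < 1.0:
            raise ValueError("g_off_fraction must be in (0, 1)")
        if self.g_on_nS <= 0 or self.g_off_neg_nS <= 0:
            raise ValueError("conductances must be positive")
        if self.mode not in ("diode", "resistor"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.interpolation != "linear":
            raise ValueError("only the linear n_Z/7 map is built in")

    # -- branch currents (pA), V in mV, vectorized over V ------------------

    def i_on(self, v_mV) -> np.ndarray:
        v = np.asarray(v_mV, dtype=float)
        if self.mode == "resistor":
            return self.g_on_nS * v
        return np.where(v >= 0, self.g_on_nS * v, self.g_on_nS * self.on_neg_ratio * v)

    def i_off(self, v_mV) -> np.ndarray:
        v = np.asarray(v_mV, dtype=float)
        if self.mode == "resistor":
            return self.g_off_fraction * self.g_on_nS * v
        # Positive branch: saturating leak anchored so i_off(+100) equals
        # g_off_fraction * i_on(+100) exactly.
        i_sat = (
            self.g_off_fraction
            * self.g_on_nS
            * 100.0
            / math.tanh(100.0 / self.rect_sat_mV)
        )
        pos = i_sat * np.tanh(v / self.rect_sat_mV)
        neg = self.g_off_neg_nS * v
        return np.where(v >= 0, pos, neg)

    def fraction_on(self, n_Z) -> np.ndarray:
        """Configuration->conductance map: weight of the ON branch (n_Z/7)."""
        return np.asarray(n_Z, dtype=float) / N_SUBUNITS

    def current(self, n_Z, v_mV, scale: float = 1.0) -> np.ndarray:
        """Single-pore current (pA) for a composition at a potential."""
        f = self.fraction_on(n_Z)
        return scale * (self.i_off(v_mV) + f * (self.i_on(v_mV) - self.i_off(v_mV)))

    @property
    def i_full_scale_pA(self) -> float:
        """Fully-ON current at +100 mV (the per-pore normalization level)."""
        return float(self.i_on(100.0))


def pore_current(
    config: PoreConfiguration | int,
    v_mV,
    model: ConductanceModel,
    scale: float = 1.0,
) -> np.ndarray:
    """Current (pA) through one pore at potential ``v_mV`` (mV).

    ``config`` may be a :class:`PoreConfiguration` or a bare n_Z count.
    Potentials beyond the characterized +/-200 mV range trigger a warning and
    linear extrapolation of the branches.
    """
    n_z = config.n_Z if isinstance(config, PoreConfiguration) else int(config)
    if not 0 <= n_z <= N_SUBUNITS:
        raise ValueError(f"n_Z must be in 0..7, got {n_z}")
    v = np.asarray(v_mV, dtype=float)
    if np.any(np.abs(v) > model.v_range_mV):
        warnings.warn(
            f"potential beyond the characterized +/-{model.v_range_mV:g} mV range; "
            "extrapolating linearly",
            stacklevel=2,
        )
    out = model.current(n_z, v, scale=scale)
    return out if out.ndim else float(out)


def rectification_ratio_model(
    model: ConductanceModel, v_mV: float, state: str = "off"
) -> float:
    """Model rectification ratio |I(-V)|/|I(+V)| for the pure ON or OFF state."""
    if v_mV <= 0:
        raise ValueError("rectification ratio requires V > 0")
    n_z = N_SUBUNITS if state.lower() == "on" else 0
    i_pos = float(model.current(n_z, +v_mV))
    i_neg = float(model.current(n_z, -v_mV))
    if i_pos == 0.0:
        return math.inf
    return abs(i_neg) / abs(i_pos)


def sample_pore_conductances(
    model: ConductanceModel, n_pores: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Per-pore ON conductances (nS) from the heterogeneity distribution.

    Draws are from a truncated normal (mean 0.62, s.d. 0.30, bounds
    0.12-1.27 nS, matching the observed single-pore range) and are
    reproducible for a given seed/generator.
    """
    if n_pores < 1:
        raise ValueError("n_pores must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return model.heterogeneity.sample(n_pores, rng)


def nand_truth_table(
    model: ConductanceModel,
    params,
    uv_nm: int = 365,
    green_nm: int = 530,
    v_mV: float = 100.0,
) -> List[Dict]:
    """Classify equilibrium currents as high/low for the four NAND inputs.

    Inputs are the irradiation wavelength (365 nm vs 530 nm) and the applied
    potential (-100 vs +100 mV); the output level is the expected per-pore
    current magnitude at the corresponding photostationary state.  The
    high/low threshold is placed in the largest gap of the four sorted
    magnitudes, which separates the single low level — occurring only at
    (530 nm, +100 mV) — from the three conducting combinations.
    """
    rows = []
    for wl in (uv_nm, green_nm):
        p_z = params.pss_Z(wl)
        f = p_z  # expected ON weight: E[n_Z]/7 under Binomial(7, p_Z)
        for v in (-abs(v_mV), +abs(v_mV)):
            i = float(model.i_off(v) + f * (model.i_on(v) - model.i_off(v)))
            rows.append(
                {"wavelength_nm": wl, "voltage_mV": v, "current_pA": i,
                 "magnitude_pA": abs(i)}
            )
    mags = sorted(r["magnitude_pA"] for r in rows)
    gaps = [mags[i + 1] - mags[i] for i in range(3)]
    k = int(np.argmax(gaps))
    threshold = 0.5 * (mags[k] + mags[k + 1])
    for r in rows:
        r["output"] = "high" if r["magnitude_pA"] > threshold else "low"
    return rows


def iv_curve_points(
    model: ConductanceModel,
    n_Z: int,
    voltages_mV: Optional[Sequence[float]] = None,
    scale: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Model I-V curve on a voltage grid (default -200..+200 mV, 10 mV steps)."""
    if voltages_mV is None:
        voltages_mV = np.arange(-200.0, 200.0 + 1e-9, 10.0)
    v = np.asarray(voltages_mV, dtype=float)
    return v, model.current(n_Z, v, scale=scale)
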