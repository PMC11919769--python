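"""Two-state photoswitch kinetics under mono- and polychromatic irradiation.

An arylazopyrazole (or azobenzene-family) photoswitch interconverts between its
*E* and *Z* isomers.  Under irradiation the isomerization rate in each
direction is linear in irradiance,

    k_EZ = sum_lambda sigma_EZ(lambda) * Q_lambda
    k_ZE = sum_lambda sigma_ZE(lambda) * Q_lambda + k_thermal_ZE,

where ``sigma_XY(lambda)`` is an effective per-wavelength cross-section in
s^-1 per (mW cm^-2) and Q is the irradiance of each LED source.  The
photostationary state (PSS) reached under continuous irradiation is the
kinetic equilibrium of this two-state system,

    p_Z(PSS) = k_EZ / (k_EZ + k_ZE),

which for a single wavelength is independent of irradiance — only the rate of
approach scales with light intensity.  Mixing two wavelengths produces PSS
fractions between the two single-wavelength values, tunable through the
intensity ratio.

The absolute rate scale is calibrated from measured switching times of the
heptameric pore: the time for all 7 independent switches of one pore to flip
once is the expected maximum of 7 i.i.d. exponential waiting times,
``H7 / k`` with ``H7 = 1 + 1/2 + ... + 1/7 ≈ 2.5929``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, Tuple

__all__ = [
    "H7",
    "LightField",
    "DARK",
    "PhotoswitchParams",
    "UnknownWavelengthError",
    "UndefinedEquilibriumError",
    "effective_rates",
    "pss_fraction_Z",
    "relax_fraction_Z",
    "calibrate_sigma_from_response_times",
    "preset",
    "PRESET_NAMES",
]

#: 7th harmonic number: expected maximum of 7 unit-rate exponential times.
H7 = sum(1.0 / i for i in range(1, 8))


class UnknownWavelengthError(KeyError):
    """A light source wavelength has no configured cross-sections."""


class UndefinedEquilibriumError(ValueError):
    """No photostationary state exists (dark field, no thermal relaxation)."""


@dataclass(frozen=True)
class LightField:
    """A set of simultaneous LED sources: (wavelength nm, irradiance mW cm^-2)."""

    sources: Tuple[Tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        norm = tuple((int(w), float(q)) for w, q in self.sources)
        for w, q in norm:
            if q < 0:
                raise ValueError(f"negative irradiance {q} at {w} nm")
        object.__setattr__(self, "sources", norm)

    @classmethod
    def single(cls, wavelength_nm: int, irradiance: float) -> "LightField":
        return cls(((wavelength_nm, irradiance),))

    @property
    def is_dark(self) -> bool:
        return all(q == 0 for _, q in self.sources) or not self.sources

    def scaled(self, factor: float) -> "LightField":
        return LightField(tuple((w, q * factor) for w, q in self.sources))

    def to_dict(self) -> list:
        return [[w, q] for w, q in self.sources]

    @classmethod
    def from_dict(cls, data: Iterable[Sequence[float]]) -> "LightField":
        return cls(tuple((int(w), float(q)) for w, q in data))


DARK = LightField()


@dataclass(frozen=True)
class PhotoswitchParams:
    """Per-wavelength isomerization parameters of one photoswitch species.

    ``sigma_EZ``/``sigma_ZE`` map wavelength (integer nm) to rate coefficients
    in s^-1 per (mW cm^-2).  Wavelengths are matched by exact integer key; no
    spectral-bandwidth model is applied (narrow bandpass filtering of the LEDs
    was found to have little effect on gating).
    """

    name: str
    sigma_EZ: Mapping[int, float]
    sigma_ZE: Mapping[int, float]
    k_thermal_ZE: float = 0.0

    def __post_init__(self) -> None:
        sez = {int(w): float(s) for w, s in self.sigma_EZ.items()}
        sze = {int(w): float(s) for w, s in self.sigma_ZE.items()}
        if set(sez) != set(sze):
            raise ValueError("sigma_EZ and sigma_ZE must cover the same wavelengths")
        for d in (sez, sze):
            for w, s in d.items():
                if s < 0:
                    raise ValueError(f"negative cross-section at {w} nm")
        if self.k_thermal_ZE < 0:
            raise ValueError("negative thermal relaxation rate")
        object.__setattr__(self, "sigma_EZ", sez)
        object.__setattr__(self, "sigma_ZE", sze)

    @property
    def wavelengths(self) -> Tuple[int, ...]:
        return tuple(sorted(self.sigma_EZ))

    def pss_Z(self, wavelength_nm: int) -> float:
        """PSS Z-fraction at a single wavelength: sigma_EZ/(sigma_EZ+sigma_ZE)."""
        w = int(wavelength_nm)
        if w not in self.sigma_EZ:
            raise UnknownWavelengthError(
                f"photoswitch {self.name!r} has no parameters for {w} nm"
            )
        tot = self.sigma_EZ[w] + self.sigma_ZE[w]
        if tot == 0:
            raise UndefinedEquilibriumError(f"zero cross-sections at {w} nm")
        return self.sigma_EZ[w] / tot

    @classmethod
    def from_pss(
        cls,
        name: str,
        pss_Z: Mapping[int, float],
        total_sigma: Mapping[int, float],
        k_thermal_ZE: float = 0.0,
    ) -> "PhotoswitchParams":
        """Build from PSS fractions and total (E->Z + Z->E) cross-sections."""
        sez, sze = {}, {}
        for w, p in pss_Z.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"PSS fraction {p} at {w} nm outside [0, 1]")
            tot = float(total_sigma[w])
            sez[int(w)] = p * tot
            sze[int(w)] = (1.0 - p) * tot
        return cls(name=name, sigma_EZ=sez, sigma_ZE=sze, k_thermal_ZE=k_thermal_ZE)


def effective_rates(params: PhotoswitchParams, light: LightField) -> Tuple[float, float]:
    """Total (k_EZ, k_ZE) in s^-1 under a light field; linear in irradiance."""
    k_ez = 0.0
    k_ze = params.k_thermal_ZE
    for w, q in light.sources:
        if w not in params.sigma_EZ:
            raise UnknownWavelengthError(
                f"photoswitch {params.name!r} has no parameters for {w} nm"
            )
        k_ez += params.sigma_EZ[w] * q
        k_ze += params.sigma_ZE[w] * q
    return k_ez, k_ze


def pss_fraction_Z(params: PhotoswitchParams, light: LightField) -> float:
    """Photostationary Z fraction k_EZ/(k_EZ + k_ZE) under a light field."""
    k_ez, k_ze = effective_rates(params, light)
    tot = k_ez + k_ze
    if tot <= 0.0:
        raise UndefinedEquilibriumError(
            "dark field with no thermal relaxation has no photostationary state"
        )
    return k_ez / tot


def relax_fraction_Z(
    params: PhotoswitchParams, light: LightField, p0: float, t: float
) -> float:
    """Z fraction after time ``t`` starting from ``p0`` (closed-form solution).

    p(t) = p_inf + (p0 - p_inf) * exp(-(k_EZ + k_ZE) t).  In the dark with no
    thermal relaxation the fraction is constant.
    """
    k_ez, k_ze = effective_rates(params, light)
    tot = k_ez + k_ze
    if tot == 0.0:
        return p0
    p_inf = k_ez / tot
    return p_inf + (p0 - p_inf) * math.exp(-tot * t)


def calibrate_sigma_from_response_times(
    pss_Z: Mapping[int, float],
    name: str = "pzMe",
    t_uv: float = 1.8,
    q_uv: float = 36.2,
    uv_nm: int = 365,
    t_green: float = 31.4,
    q_green: float = 30.3,
    green_nm: int = 530,
    k_thermal_ZE: float = 0.0,
) -> PhotoswitchParams:
    """Set absolute cross-sections from two measured pore switching times.

    The switching time of a 7-switch pore is modelled as the expected maximum
    of 7 i.i.d. exponential flips, ``H7 / k``, where ``k`` is the per-switch
    rate of the light-driven direction at that wavelength (E->Z under UV,
    Z->E under green).  The opposite-direction cross-section at each anchor
    follows from the configured PSS fraction.  Cross-sections at other
    configured wavelengths are scaled by log-linear interpolation (in
    wavelength) of the total cross-section per unit irradiance between the
    two anchors.
    """
    if t_uv <= 0 or t_green <= 0:
        raise ValueError("response times must be positive")
    if q_uv <= 0 or q_green <= 0:
        raise ValueError("calibration irradiances must be positive")
    pss = {int(w): float(p) for w, p in pss_Z.items()}
    for anchor in (uv_nm, green_nm):
        if anchor not in pss:
            raise ValueError(f"PSS fraction at anchor wavelength {anchor} nm required")

    # Anchor: dominant-direction per-switch rates from the printed times.
    k_uv = H7 / t_uv            # E->Z rate at uv_nm, q_uv
    k_green = H7 / t_green      # Z->E rate at green_nm, q_green
    sigma_ez_uv = k_uv / q_uv
    p_uv = pss[uv_nm]
    if not 0.0 < p_uv <= 1.0:
        raise ValueError("UV-anchor PSS Z fraction must be in (0, 1]")
    tot_uv = sigma_ez_uv / p_uv

    sigma_ze_green = k_green / q_green
    p_green = pss[green_nm]
    if not 0.0 <= p_green < 1.0:
        raise ValueError("green-anchor PSS Z fraction must be in [0, 1)")
    tot_green = sigma_ze_green / (1.0 - p_green)

    def total_sigma_at(w: int) -> float:
        if w == uv_nm:
            return tot_uv
        if w == green_nm:
            return tot_green
        x = (w - uv_nm) / (green_nm - uv_nm)
        return math.exp(
            (1.0 - x) * math.log(tot_uv) + x * math.log(tot_green)
        )

    totals = {w: total_sigma_at(w) for w in pss}
    return PhotoswitchParams.from_pss(
        name, pss, totals, k_thermal_ZE=k_thermal_ZE
    )


# ---------------------------------------------------------------------------
# Built-in presets
# ---------------------------------------------------------------------------

# Measured PSS isomer fractions (Z fraction by wavelength).  pzMe: 96% Z at
# 365 nm, 93% E at 530 nm; fAzo: 85% E at 405 nm, 91% Z at 530 nm; pzH: 65% E
# at 365 nm, 85% Z at 530 nm (the latter two invert the pzMe pattern and are
# stored verbatim).  The pzMe values at 405/455 nm are not measured; the
# defaults below are chosen so the four wavelengths produce ordered
# intermediate current levels (365 > 405 > 455 > 530 in Z fraction).
_PRESET_PSS = {
    "pzMe": {365: 0.96, 405: 0.70, 455: 0.45, 530: 0.07},
    "pzH": {365: 0.35, 530: 0.85},
    "fAzo": {405: 0.15, 530: 0.91},
}

PRESET_NAMES = tuple(_PRESET_PSS)


def preset(name: str = "pzMe") -> PhotoswitchParams:
    """A calibrated built-in photoswitch parameter set.

    All presets use the measured pore switching times of the methylated
    arylazopyrazole for the absolute rate scale (1.8 s at 36.2 mW cm^-2 of
    365 nm light; 31.4 s at 30.3 mW cm^-2 of 530 nm), and zero thermal Z->E
    relaxation (none observed over an hour in the dark).
    """
    try:
        pss = _PRESET_PSS[name]
    except KeyError:
        raise KeyError(
            f"unknown photoswitch preset {name!r}; available: {sorted(_PRESET_PSS)}"
        ) from None
    uv = 365 if 365 in pss else min(pss)
    return calibrate_sigma_from_response_times(pss, name=name, uv_nm=uv)
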