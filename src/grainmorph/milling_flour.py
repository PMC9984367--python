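"""Milling energy, flour particle-size summaries, and gelatinization range.

Specific milling energy normalizes the mill's net energy draw by grain
mass: ``E_r = (E_c - E_s) / m_g`` (kJ/kg), where ``E_s`` is the idle energy
(idle power × milling time) subtracted from the total ``E_c``.

Laser-diffraction particle-size distributions are summarized by the volume
percentiles d(0.1), d(0.5), d(0.9), the volume-weighted mean size
``d_avg = Σ φ_i·d_i``, and the relative distribution width
``SPAN = (d(0.9) - d(0.1)) / d(0.5)``.

Differential scanning calorimetry endpoints of starch gelatinization —
onset ``T_o``, peak ``T_p`` and end ``T_e`` — are kept as a record with the
gelatinization temperature range ``ΔT = T_e - T_o``. (Some instrument
reports write the end temperature as ``T_c``; it is canonicalized to
``T_e`` here.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MillingRecord",
    "PSDSummary",
    "DSCRecord",
    "specific_milling_energy",
    "psd_summary",
    "span",
    "dsc_delta",
]


def span(d10: float, d50: float, d90: float) -> float:
    """Relative distribution width ``(d(0.9) - d(0.1)) / d(0.5)``."""
    if not d10 <= d50 <= d90:
        raise ValueError("percentiles must satisfy d10 ≤ d50 ≤ d90")
    if d50 <= 0:
        raise ValueError("d50 must be positive")
    return (d90 - d10) / d50


@dataclass(frozen=True)
class MillingRecord:
    """One milling run: total energy, idle power, time and grain mass."""

    E_c_kJ: float
    idle_power_kW: float
    time_s: float
    mass_kg: float

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError("mass_kg must be positive")
        if self.idle_power_kW < 0 or self.time_s < 0:
            raise ValueError("idle power and time must be non-negative")

    @property
    def E_s_kJ(self) -> float:
        """Idle energy: idle power (kW) × milling time (s) = kJ."""
        return self.idle_power_kW * self.time_s


def specific_milling_energy(rec: MillingRecord) -> float:
    """Net milling energy per unit grain mass, ``(E_c - E_s)/m_g`` (kJ/kg)."""
    if rec.E_c_kJ < rec.E_s_kJ:
        raise ValueError(
            f"total energy {rec.E_c_kJ} kJ is below idle energy "
            f"{rec.E_s_kJ} kJ: inconsistent measurement"
        )
    return (rec.E_c_kJ - rec.E_s_kJ) / rec.mass_kg


@dataclass(frozen=True)
class PSDSummary:
    d10: float  # µm
    d50: float
    d90: float
    d_avg: float
    span: float


def psd_summary(
    sizes_um: np.ndarray,
    volume_fractions: np.ndarray,
    log_axis: bool = True,
) -> PSDSummary:
    """Percentiles, mean size and SPAN of a volume-fraction histogram.

    The cumulative volume curve is evaluated at bin centers with the
    midpoint convention (cumulative up to a bin minus half the bin's own
    fraction) and the percentiles are found by linear interpolation,
    against log size by default (the laser-diffraction convention) or
    linear size with ``log_axis=False``.

    Parameters
    ----------
    sizes_um : array
        Bin-center particle sizes, µm; sorted ascending (unsorted input is
        sorted with a warning).
    volume_fractions : array
        Non-negative, summing to 1 within 1e-6 (then renormalized exactly).
    """
    sizes = np.asarray(sizes_um, dtype=float)
    fracs = np.asarray(volume_fractions, dtype=float)
    if sizes.shape != fracs.shape or sizes.ndim != 1 or sizes.size == 0:
        raise ValueError("sizes and fractions must be equal-length 1-D arrays")
    if np.any(fracs < 0):
        raise ValueError("volume fractions must be non-negative")
    total = fracs.sum()
    if total == 0:
        raise ValueError("all volume fractions are zero")
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"volume fractions sum to {total}, not 1")
    fracs = fracs / total
    if np.any(np.diff(sizes) < 0):
        warnings.warn("sizes were not sorted ascending; sorting")
        order = np.argsort(sizes)
        sizes, fracs = sizes[order], fracs[order]
    if np.any(sizes <= 0):
        raise ValueError("particle sizes must be positive")

    d_avg = float(np.sum(fracs * sizes))
    if sizes.size == 1:
        d = float(sizes[0])
        return PSDSummary(d10=d, d50=d, d90=d, d_avg=d_avg, span=0.0)

    cum_mid = np.cumsum(fracs) - fracs / 2.0
    axis = np.log(sizes) if log_axis else sizes

    def quantile(q: float) -> float:
        x = float(np.interp(q, cum_mid, axis))
        return float(np.exp(x)) if log_axis else x

    d10, d50, d90 = quantile(0.1), quantile(0.5), quantile(0.9)
    return PSDSummary(
        d10=d10, d50=d50, d90=d90, d_avg=d_avg, span=(d90 - d10) / d50
    )


@dataclass(frozen=True)
class DSCRecord:
    """Gelatinization endotherm endpoints (°C) and enthalpy (J/g)."""

    T_o: float
    T_p: float
    T_e: float
    dH: float | None = None
    dT: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.T_o <= self.T_p <= self.T_e):
            raise ValueError("temperatures must satisfy T_o ≤ T_p ≤ T_e")
        object.__setattr__(self, "dT", self.T_e - self.T_o)


def dsc_delta(rec: DSCRecord) -> float:
    """Gelatinization temperature range ``ΔT = T_e - T_o`` (°C)."""
    return rec.dT
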