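"""Incubation CO2 flux math: headspace respiration rates and Q10.

A sealed jar of soil accumulates CO2 between flushes; the headspace mixing
ratio (ppm = umol CO2 per mol air), jar pressure, headspace volume and
temperature give the moles of CO2 via the ideal gas law, which normalized by
dry soil mass and the flush-to-flush interval yields a respiration rate in
ug C-CO2 per g dry soil per hour:

    rate = co2_ppm * (P*V)/(R*T) * (1/g dry soil) * 12 ug C/umol C * (1/t)

Temperature sensitivity between paired incubations at 4 C and 15 C:

    Q10 = (k15/k4) ** (10 / (15 - 4))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GAS_CONSTANT",
    "GasMeasurement",
    "RatePair",
    "respiration_rate",
    "mean_stabilized_rate",
    "q10",
]

#: ideal gas constant, L atm K^-1 mol^-1
GAS_CONSTANT = 0.0821
#: ug C per umol C
_UG_C_PER_UMOL = 12.0


@dataclass(frozen=True)
class GasMeasurement:
    """One headspace CO2 reading and the jar's physical state."""

    co2_ppm: float  # umol CO2 / mol air
    pressure_atm: float = 1.0
    headspace_volume_l: float = 1.0
    temperature_k: float = 277.15
    dry_soil_g: float = 10.0
    interval_h: float = 24.0
    day: float = 0.0
    gas_constant: float = GAS_CONSTANT
    below_detection: bool = False  # excluded from analysis, never imputed

    def __post_init__(self):
        if self.co2_ppm < 0:
            raise ValueError("co2_ppm must be nonnegative")
        for name in (
            "pressure_atm",
            "headspace_volume_l",
            "dry_soil_g",
            "interval_h",
            "gas_constant",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.temperature_k <= 250:
            raise ValueError("temperature_k must exceed 250 K")


@dataclass(frozen=True)
class RatePair:
    """Respiration rates at the warm and cold incubation temperatures."""

    k15: float
    k4: float


def respiration_rate(m: GasMeasurement) -> float:
    """Respiration rate in ug C-CO2 g^-1 dry soil h^-1 from one reading.

    Linear in ``co2_ppm`` and inversely linear in dry soil mass and the
    accumulation interval.
    """
    mol_air = m.pressure_atm * m.headspace_volume_l / (m.gas_constant * m.temperature_k)
    umol_co2 = m.co2_ppm * mol_air
    return umol_co2 * _UG_C_PER_UMOL / (m.dry_soil_g * m.interval_h)


def mean_stabilized_rate(
    series,
    window_start_day: float = 20.0,
    window_end_day: float = 193.0,
) -> float:
    """Arithmetic mean rate over the stabilized window (default day 20-193).

    ``series`` is an iterable of (day, rate) pairs or a DataFrame with ``day``
    and ``rate`` columns. Raises if no measurement falls in the window.
    """
    if isinstance(series, pd.DataFrame):
        days = series["day"].to_numpy(dtype=float)
        rates = series["rate"].to_numpy(dtype=float)
    else:
        pairs = list(series)
        days = np.array([p[0] for p in pairs], dtype=float)
        rates = np.array([p[1] for p in pairs], dtype=float)
    keep = (days >= window_start_day) & (days <= window_end_day)
    if not keep.any():
        raise ValueError(
            f"no measurements in the stabilized window "
            f"[{window_start_day}, {window_end_day}]"
        )
    return float(rates[keep].mean())


def q10(rates: RatePair, t_high_c: float = 15.0, t_low_c: float = 4.0) -> float:
    """Temperature sensitivity Q10 = (k_high/k_low)**(10/(t_high - t_low)).

    With the default 15 C / 4 C pairing the exponent is 10/11. Scale-invariant
    in the rates; swapping both rates and temperatures inverts the result.
    """
    if rates.k15 <= 0 or rates.k4 <= 0:
        raise ValueError("both rates must be strictly positive")
    if t_high_c == t_low_c:
        raise ValueError("the two incubation temperatures must differ")
    return float((rates.k15 / rates.k4) ** (10.0 / (t_high_c - t_low_c)))
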