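"""Drift-tube ion mobility CCS determination (Mason-Schamp), stepped and single field.

Two routes from arrival time to a rotationally averaged collision cross
section (CCS, in A^2) in nitrogen drift gas:

* **Stepped (multi-) field**: arrival times measured at several drift voltages
  are regressed against 1/V; the slope gives the mobility K (the intercept
  absorbs the instrument dead time t_fix), K is normalized to the reduced
  mobility K0 at 273.15 K / 760 Torr, and the Mason-Schamp equation converts
  K0 to CCS.

* **Single field**: reference ions of known CCS (tune-mix calibrants) fit the
  linear model  t_A = beta * gamma * CCS + t_fix  with gamma = sqrt(mu)/|z|,
  mu the ion-gas reduced mass.  The fitted (beta, t_fix) then map arrival
  times of analytes to CCS and back.

All forward/inverse pairs here are algebraically exact inverses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "N2_MASS",
    "DriftGasState",
    "SteppedFieldSeries",
    "SteppedFieldResult",
    "SingleFieldCalibration",
    "ReferenceIon",
    "TUNE_MIX_NEGATIVE",
    "TUNE_MIX_POSITIVE",
    "reduced_mass",
    "mason_schamp_ccs",
    "ccs_to_k0",
    "stepped_field_fit",
    "single_field_calibrate",
    "arrival_time_to_ccs",
    "ccs_to_arrival_time",
    "ccs_deviation",
]

# Physical constants (SI)
ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
LOSCHMIDT = 2.6867811e25  # m^-3, gas number density at 273.15 K / 760 Torr
DA_TO_KG = 1.66053906660e-27

#: monoisotopic mass of N2 drift gas, Da
N2_MASS = 28.006148

STANDARD_TEMPERATURE = 273.15  # K
STANDARD_PRESSURE = 760.0  # Torr


@dataclass(frozen=True)
class DriftGasState:
    """Drift gas composition and tube conditions.

    The tube temperature is not independently measured here; 305 K is the
    assumed default and cancels in all calibration roundtrips.
    """

    gas_mass: float = N2_MASS  # Da
    temperature: float = 305.0  # K
    pressure: float = 3.95  # Torr

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.pressure <= 0 or self.gas_mass <= 0:
            raise ValueError("gas mass, temperature and pressure must be positive")


def reduced_mass(ion_mass: float, gas_mass: float = N2_MASS) -> float:
    """Ion-gas reduced mass mu = m*M/(m+M), in Da."""
    if ion_mass <= 0 or gas_mass <= 0:
        raise ValueError("masses must be positive")
    return ion_mass * gas_mass / (ion_mass + gas_mass)


def _mason_schamp_prefactor(ion_mass: float, charge: int, gas: DriftGasState) -> float:
    """CCS * K0 product (in A^2 * cm^2/(V s)) at the gas temperature."""
    mu_kg = reduced_mass(ion_mass, gas.gas_mass) * DA_TO_KG
    omega_k0 = (
        (3.0 * abs(charge) * ELEMENTARY_CHARGE / (16.0 * LOSCHMIDT))
        * math.sqrt(2.0 * math.pi / (mu_kg * BOLTZMANN * gas.temperature))
    )  # m^2 * (m^2/Vs)
    return omega_k0 * 1e20 * 1e4  # -> A^2 * cm^2/(V s)


def mason_schamp_ccs(
    k0: float, ion_mass: float, charge: int = 1, gas: DriftGasState | None = None
) -> float:
    """CCS (A^2) from the reduced mobility K0 (cm^2 V^-1 s^-1)."""
    if k0 <= 0:
        raise ValueError(f"reduced mobility must be positive, got {k0}")
    gas = gas or DriftGasState()
    return _mason_schamp_prefactor(ion_mass, charge, gas) / k0


def ccs_to_k0(
    ccs: float, ion_mass: float, charge: int = 1, gas: DriftGasState | None = None
) -> float:
    """Inverse of :func:`mason_schamp_ccs`."""
    if ccs <= 0:
        raise ValueError(f"CCS must be positive, got {ccs}")
    gas = gas or DriftGasState()
    return _mason_schamp_prefactor(ion_mass, charge, gas) / ccs


@dataclass(frozen=True)
class SteppedFieldSeries:
    """Arrival times (ms) at several drift voltages (V), at fixed T, P."""

    voltages: tuple[float, ...]
    arrival_times_ms: tuple[float, ...]
    tube_length_m: float = 0.7803  # drift-tube length
    gas: DriftGasState = field(default_factory=DriftGasState)

    def __post_init__(self) -> None:
        if len(self.voltages) != len(self.arrival_times_ms):
            raise ValueError("voltages and arrival times differ in length")
        if len(set(self.voltages)) < 3:
            raise ValueError("stepped-field fit needs >= 3 distinct drift voltages")


@dataclass(frozen=True)
class SteppedFieldResult:
    k0: float  # cm^2/(V s)
    ccs: float  # A^2
    t_fix_ms: float
    r_squared: float


def stepped_field_fit(
    series: SteppedFieldSeries, ion_mass: float, charge: int = 1
) -> SteppedFieldResult:
    """Fit t_A = L^2/(K V) + t_fix over the voltage steps and convert to K0/CCS.

    K at tube conditions is normalized to K0 at 273.15 K / 760 Torr before the
    Mason-Schamp conversion.
    """
    x = 1.0 / np.asarray(series.voltages, dtype=float)
    y = np.asarray(series.arrival_times_ms, dtype=float) * 1e-3  # s
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise ValueError("non-physical fit: arrival time must grow with 1/V")
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    k = series.tube_length_m**2 / slope  # m^2/(V s) at tube T, P
    gas = series.gas
    k0 = (
        k
        * (gas.pressure / STANDARD_PRESSURE)
        * (STANDARD_TEMPERATURE / gas.temperature)
        * 1e4
    )  # cm^2/(V s)
    ccs = mason_schamp_ccs(k0, ion_mass, charge, gas)
    return SteppedFieldResult(k0=k0, ccs=ccs, t_fix_ms=intercept * 1e3, r_squared=r2)


@dataclass(frozen=True)
class ReferenceIon:
    """A calibrant ion of known m/z and CCS, with its measured arrival time."""

    mz: float
    charge: int
    ccs: float  # A^2
    arrival_time_ms: float


#: Agilent tune-mix reference ions used by the single-field calibration
#: (hexakis(1H,1H,3H-perfluoropropoxy)phosphazene, [M+H]+ and [M+TFA-H]-).
TUNE_MIX_POSITIVE: tuple[tuple[float, int, float], ...] = (
    (922.009799, +1, 243.64),
)
TUNE_MIX_NEGATIVE: tuple[tuple[float, int, float], ...] = (
    (1033.987012, -1, 255.34),
)


@dataclass(frozen=True)
class SingleFieldCalibration:
    """Linear arrival-time model t_A = beta * gamma * CCS + t_fix."""

    beta: float
    t_fix_ms: float
    gas: DriftGasState = field(default_factory=DriftGasState)
    residuals_ms: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("calibration slope beta must be positive")

    def gamma(self, mz: float, charge: int = 1) -> float:
        return math.sqrt(reduced_mass(abs(charge) * mz, self.gas.gas_mass)) / abs(charge)

    def to_file(self, path: str | Path) -> None:
        payload = {
            "beta": self.beta,
            "t_fix_ms": self.t_fix_ms,
            "gas_mass": self.gas.gas_mass,
            "temperature_K": self.gas.temperature,
            "pressure_Torr": self.gas.pressure,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SingleFieldCalibration":
        d = json.loads(Path(path).read_text())
        gas = DriftGasState(d["gas_mass"], d["temperature_K"], d["pressure_Torr"])
        return cls(beta=d["beta"], t_fix_ms=d["t_fix_ms"], gas=gas)


def single_field_calibrate(
    references: Sequence[ReferenceIon], gas: DriftGasState | None = None
) -> SingleFieldCalibration:
    """Least-squares (beta, t_fix) from >= 2 reference ions of known CCS."""
    if len(references) < 2:
        raise ValueError("single-field calibration needs >= 2 reference ions")
    gas = gas or DriftGasState()
    x = np.array(
        [
            math.sqrt(reduced_mass(abs(r.charge) * r.mz, gas.gas_mass))
            / abs(r.charge)
            * r.ccs
            for r in references
        ]
    )
    if np.ptp(x) <= 0:
        raise ValueError("degenerate calibration: gamma*CCS values coincide")
    y = np.array([r.arrival_time_ms for r in references])
    beta, t_fix = np.polyfit(x, y, 1)
    residuals = tuple(float(v) for v in (y - (beta * x + t_fix)))
    return SingleFieldCalibration(beta=beta, t_fix_ms=t_fix, gas=gas, residuals_ms=residuals)


def arrival_time_to_ccs(
    t_arrival_ms: float, calib: SingleFieldCalibration, mz: float, charge: int = 1
) -> float:
    """CCS = (t_A - t_fix) / (beta * gamma)."""
    if t_arrival_ms <= calib.t_fix_ms:
        raise ValueError(
            f"arrival time {t_arrival_ms} ms is not after the dead time "
            f"{calib.t_fix_ms} ms"
        )
    return (t_arrival_ms - calib.t_fix_ms) / (calib.beta * calib.gamma(mz, charge))


def ccs_to_arrival_time(
    ccs: float, calib: SingleFieldCalibration, mz: float, charge: int = 1
) -> float:
    """Exact inverse of :func:`arrival_time_to_ccs`."""
    if ccs <= 0:
        raise ValueError(f"CCS must be positive, got {ccs}")
    return calib.beta * calib.gamma(mz, charge) * ccs + calib.t_fix_ms


def ccs_deviation(stepped: float, single: float) -> float:
    """Percent deviation of the single-field CCS from the stepped-field value."""
    if stepped <= 0 or single <= 0:
        raise ValueError("CCS values must be positive")
    return round(100.0 * (single - stepped) / stepped, 2)
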