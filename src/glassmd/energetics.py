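"""Vaporization and fusion energetics from ensemble energy series.

The molar vaporization energy is the cohesive-energy difference between an
isolated molecule (the ideal-vapor reference, an intramolecular-only
average) and the bulk liquid per molecule,

    U_vap = <U_gas> - <U_liq>/n,

and the enthalpy follows from the ideal-gas law, dH_vap = U_vap + R*T.
The fusion enthalpy is a plain two-phase per-molecule enthalpy difference
at a common temperature, without superheating corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_io import ThermoSeries

__all__ = [
    "R_KJ_PER_MOL_K",
    "VaporizationResult",
    "FusionResult",
    "vaporization_energy",
    "specific_energy",
    "fusion_enthalpy",
]

R_KJ_PER_MOL_K = 8.31446e-3   # gas constant, kJ/(mol K)


@dataclass
class VaporizationResult:
    """Molar vaporization energy/enthalpy (kJ/mol) with combined sd."""

    U_vap: float
    U_vap_sd: float
    H_vap: float
    H_vap_sd: float
    temperature: float


@dataclass
class FusionResult:
    """Per-molecule fusion enthalpy (kJ/mol) at a stated temperature."""

    H_fus: float
    temperature: float
    phases: tuple[str, str] = ("crystal", "liquid")


def _mean_and_sem(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    sem = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return float(x.mean()), sem


def vaporization_energy(liquid: ThermoSeries, gas: ThermoSeries,
                        n_molecules_liquid: int,
                        temperature: float) -> VaporizationResult:
    """Vaporization energy and enthalpy from liquid-box and gas series.

    ``liquid.potential_energy`` is per simulation box (divided by
    ``n_molecules_liquid``); ``gas.potential_energy`` is already per
    molecule (a single-molecule run).  Standard errors of the two means
    combine in quadrature.  Temperature metadata of the two series, when
    present, must agree with ``temperature`` within 1 K.
    """
    for series, label in ((liquid, "liquid"), (gas, "gas")):
        if series.temperature is not None:
            t_mean = float(np.mean(series.temperature))
            if abs(t_mean - temperature) > 1.0:
                raise ValueError(
                    f"{label} series temperature {t_mean:.1f} K does not "
                    f"match the stated {temperature:.1f} K")
    if liquid.potential_energy is None or gas.potential_energy is None:
        raise ValueError("both series need a potential-energy column")
    u_liq, se_liq = _mean_and_sem(liquid.potential_energy)
    u_gas, se_gas = _mean_and_sem(gas.potential_energy)
    u_vap = u_gas - u_liq / n_molecules_liquid
    sd = float(np.hypot(se_gas, se_liq / n_molecules_liquid))
    rt = R_KJ_PER_MOL_K * temperature
    return VaporizationResult(U_vap=u_vap, U_vap_sd=sd,
                              H_vap=u_vap + rt, H_vap_sd=sd,
                              temperature=temperature)


def specific_energy(u_vap: float, molar_mass: float,
                    unit: str = "kJ/g") -> float:
    """Vaporization energy per unit mass.

    With ``u_vap`` in kJ/mol and ``molar_mass`` in g/mol the natural scale
    is kJ/g (``unit="kJ/g"``, the default); ``unit="J/g"`` multiplies by
    1000.  Specific cohesion numbers for small organics near 100 kJ/mol
    and 100-250 g/mol land around 0.4-1 on the kJ/g scale.
    """
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    value = u_vap / molar_mass
    if unit == "kJ/g":
        return value
    if unit == "J/g":
        return value * 1000.0
    raise ValueError(f"unknown unit {unit!r}")


def fusion_enthalpy(crystal: ThermoSeries, liquid: ThermoSeries,
                    n_crystal: int, n_liquid: int,
                    temperature: float) -> FusionResult:
    """Fusion enthalpy as the liquid-minus-crystal per-molecule enthalpy.

    Both series must carry an enthalpy column and, when temperature
    metadata is present, agree with ``temperature`` within 1 K.
    """
    for series, label in ((crystal, "crystal"), (liquid, "liquid")):
        if series.temperature is not None:
            t_mean = float(np.mean(series.temperature))
            if abs(t_mean - temperature) > 1.0:
                raise ValueError(
                    f"{label} series temperature {t_mean:.1f} K does not "
                    f"match the stated {temperature:.1f} K")
        if series.enthalpy is None:
            raise ValueError(f"{label} series needs an enthalpy column")
    h_liq = float(np.mean(liquid.enthalpy)) / n_liquid
    h_cry = float(np.mean(crystal.enthalpy)) / n_crystal
    return FusionResult(H_fus=h_liq - h_cry, temperature=temperature)
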