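"""Hansen solubility parameter, Flory-Huggins chi, Flory-Rehner swelling,
and the Fujita free-volume diffusion model.

The Hansen parameter is delta = sqrt(CED) in MPa^0.5, with the cohesive
energy density CED = |E_nb| / V converted from the declared per-mole energy
unit and Angstrom^3 (or nm^3) cell volume to MPa. Nonbonded energies from
force fields are typically negative (attractive); their magnitude enters the
CED under the default sign convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from gelkit.structure_io import AVOGADRO, ThermoSeries
from gelkit.thermoanalysis import linear_fit_anova

R_GAS = 8.31446261815324  # J/(mol K)

#: Joules per mole for supported energy units.
ENERGY_UNIT_J_PER_MOL = {
    "kcal/mol": 4184.0,
    "kJ/mol": 1000.0,
    "J/mol": 1.0,
}

#: Cubic metres for supported volume units.
VOLUME_UNIT_M3 = {
    "A^3": 1e-30,
    "nm^3": 1e-27,
}


@dataclass(frozen=True)
class SolubilityResult:
    """Per-frame and averaged Hansen solubility parameter (MPa^0.5)."""

    delta_mean: float
    delta_sd: float
    per_frame: tuple[float, ...]
    ced_mean: float  # MPa


@dataclass(frozen=True)
class SwellingModel:
    """Flory-Huggins / Flory-Rehner quantities for a polymer-solvent pair."""

    chi: float
    delta_solvent: float
    delta_polymer: float
    v_solvent_molar: float  # cm^3/mol
    temperature: float  # K
    crosslink_density: float | None = None
    polymer_volume_fraction: float | None = None
    polymer_molar_fraction: float | None = None
    swelling_degree_value: float | None = None


@dataclass(frozen=True)
class DiffusionModel:
    """Fujita free-volume model: D = D0 * R * T * A * exp(-B / FFV).

    From linearized data only the composite intercept
    C = ln(D0 * R * A) and the free-volume constant B are identifiable.
    """

    B: float
    C: float
    B_se: float = float("nan")
    C_se: float = float("nan")
    D0: float | None = None
    A: float | None = None

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError("B must be positive for a physical free-volume model")


def ced_mpa(energy: float, volume: float, energy_unit: str, volume_unit: str) -> float:
    """Cohesive energy density in MPa from per-mole energy and cell volume."""
    try:
        e_j = energy * ENERGY_UNIT_J_PER_MOL[energy_unit]
    except KeyError:
        raise ValueError(f"unsupported energy unit {energy_unit!r}") from None
    try:
        v_m3 = volume * VOLUME_UNIT_M3[volume_unit]
    except KeyError:
        raise ValueError(f"unsupported volume unit {volume_unit!r}") from None
    # energy is per mole of simulation cells; volume is per cell
    return e_j / AVOGADRO / v_m3 / 1e6


def hansen_delta(
    series: ThermoSeries,
    cohesive_sign: Literal["magnitude", "positive"] = "magnitude",
    average: Literal["mean-of-sqrt", "sqrt-of-mean"] = "mean-of-sqrt",
) -> SolubilityResult:
    """Hansen solubility parameter from per-frame nonbonded energy and volume.

    ``cohesive_sign='magnitude'`` (default) takes |E_nb| as the cohesive
    energy; ``'positive'`` requires the energies to already be
    positive-signed and errors otherwise. ``average`` selects whether the
    reported mean is the mean of per-frame sqrt(CED) (default) or the square
    root of the mean CED.
    """
    E = series.column("nonbonded_energy")
    V = series.column("volume")
    e_unit = series.units.get("nonbonded_energy", "kcal/mol")
    v_unit = series.units.get("volume", "A^3")
    ceds = []
    for i, (e, v) in enumerate(zip(E, V)):
        if cohesive_sign == "magnitude":
            e = abs(e)
        elif e < 0:
            raise ValueError(
                f"negative cohesive energy at frame {i} under 'positive' convention"
            )
        ceds.append(ced_mpa(e, v, e_unit, v_unit))
    ceds = np.asarray(ceds)
    deltas = np.sqrt(ceds)
    if average == "mean-of-sqrt":
        mean = float(deltas.mean())
    elif average == "sqrt-of-mean":
        mean = float(math.sqrt(ceds.mean()))
    else:
        raise ValueError(f"unknown averaging mode {average!r}")
    sd = float(deltas.std(ddof=1)) if len(deltas) > 1 else 0.0
    return SolubilityResult(
        delta_mean=mean,
        delta_sd=sd,
        per_frame=tuple(float(d) for d in deltas),
        ced_mean=float(ceds.mean()),
    )


def chi_parameter(
    delta_s: float, delta_p: float, v_solvent_molar: float, temperature: float
) -> float:
    """Flory-Huggins chi = V (delta_s - delta_p)^2 / (R T).

    ``delta`` values in MPa^0.5, ``v_solvent_molar`` in cm^3/mol, T in K.
    (cm^3/mol x MPa) / (J/(mol K) x K) is dimensionless without further
    factors since 1 cm^3 * 1 MPa = 1 J.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if v_solvent_molar <= 0:
        raise ValueError("solvent molar volume must be positive")
    return v_solvent_molar * (delta_s - delta_p) ** 2 / (R_GAS * temperature)


def flory_rehner_crosslink(
    v_s: float, chi: float, v_solvent_molar: float, phi: float
) -> float:
    """Crosslink density d = [ln(1-v_s) + v_s + chi v_s^2] / (V_sol [v_s^(1/3) - 2 v_s phi]).

    ``v_s`` is the polymer volume fraction at equilibrium swelling, ``phi``
    the polymer molar fraction, ``v_solvent_molar`` the solvent molar volume.
    The expression is evaluated exactly as stated; near the denominator zero
    the sign of d flips, so a singular denominator raises.
    """
    if not 0 < v_s < 1:
        raise ValueError("polymer volume fraction must lie in (0, 1)")
    numerator = math.log(1.0 - v_s) + v_s + chi * v_s**2
    denominator = v_solvent_molar * (v_s ** (1.0 / 3.0) - 2.0 * v_s * phi)
    if abs(denominator) < 1e-12:
        raise ValueError("Flory-Rehner denominator is singular for these inputs")
    return numerator / denominator


def swelling_degree(v_s: float) -> float:
    """Equilibrium swelling degree Q = 1 / v_s."""
    if v_s <= 0:
        raise ValueError("polymer volume fraction must be positive")
    return 1.0 / v_s


def fujita_forward(D0: float, A: float, B: float, ffv, temperature) -> np.ndarray:
    """Self-diffusion coefficient D = D0 * R * T * A * exp(-B / FFV)."""
    ffv = np.asarray(ffv, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    if np.any(ffv <= 0):
        raise ValueError("FFV must be positive")
    if np.any(temperature <= 0):
        raise ValueError("temperature must be positive")
    return D0 * R_GAS * temperature * A * np.exp(-B / ffv)


def fujita_fit(D, ffv, temperature) -> DiffusionModel:
    """Fit ln D = C + ln T - B / FFV by least squares; returns (C, B) with SEs.

    This is the exact logarithm of the forward model, so on noiseless data
    the fit inverts :func:`fujita_forward` up to the identifiable composite
    C = ln(D0 * R * A).
    """
    D = np.asarray(D, dtype=float)
    ffv = np.asarray(ffv, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    if len(D) < 3:
        raise ValueError("fit needs at least 3 observations")
    if np.any(D <= 0) or np.any(ffv <= 0) or np.any(temperature <= 0):
        raise ValueError("D, FFV and temperature must be positive")
    x = 1.0 / ffv
    if np.allclose(x, x[0]):
        raise ValueError("collinear design: FFV does not vary")
    y = np.log(D) - np.log(temperature)
    fit = linear_fit_anova(x, y)
    return DiffusionModel(
        B=-fit.slope, C=fit.intercept, B_se=fit.slope_se, C_se=fit.intercept_se
    )
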