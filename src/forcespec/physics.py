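"""Closed-form single-bond physics and unit-safe thermodynamic conversions.

This module collects the small set of analytic models that the rest of the
package is built on:

* worm-like-chain (WLC) tether elasticity (interpolation formula),
* Bell force-activated unbinding kinetics,
* the Friddle-Noy-de Yoreo (FNdY) mean rupture force versus loading rate,
* conversions between equilibrium force, binding free energy ``deltaG_bu``,
  dissociation constant ``Kd`` and bond half-life ``tau_0.5``.

Internal energy unit is pN*nm; free energies are reported in kcal/mol
(1 kcal/mol = 6.9477 pN*nm per molecule). Pulling forces are positive and
``deltaG_bu`` is negative for favourable binding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KB_PN_NM_PER_K",
    "KCAL_PER_MOL_IN_PN_NM",
    "EULER_GAMMA",
    "ThermoConstants",
    "WLCModel",
    "BellModel",
    "FNdYModel",
    "ThermoResult",
    "wlc_force",
    "wlc_stiffness",
    "bell_off_rate",
    "fndy_mean_force",
    "deltaG_from_Feq",
    "feq_from_deltaG",
    "kd_from_deltaG",
    "deltaG_from_kd",
    "tau_half",
]

#: Boltzmann constant in pN*nm/K.
KB_PN_NM_PER_K = 0.0138065
#: One kcal/mol expressed in pN*nm per molecule.
KCAL_PER_MOL_IN_PN_NM = 6.9477
#: Euler-Mascheroni constant (enters the FNdY mean-force interpolation).
EULER_GAMMA = 0.5772156649015329


@dataclass(frozen=True)
class ThermoConstants:
    """Temperature and unit conversions shared by all calculations.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Default 297.15 K (room temperature,
        ~24 degC, the condition of the AFM experiments this package models).
    v_water : float
        Partial molar volume of water in l/mol, the reference volume in the
        free-energy/dissociation-constant relation
        ``deltaG_bu = kBT * ln(v_water * Kd)``.
    """

    temperature: float = 297.15
    v_water: float = 0.018

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.v_water <= 0:
            raise ValueError(f"v_water must be > 0 l/mol, got {self.v_water}")

    @property
    def kBT(self) -> float:
        """Thermal energy in pN*nm."""
        return KB_PN_NM_PER_K * self.temperature

    @property
    def kBT_kcal_mol(self) -> float:
        """Thermal energy in kcal/mol."""
        return self.kBT / KCAL_PER_MOL_IN_PN_NM

    def to_dict(self) -> dict:
        """Constants echoed into result records for provenance."""
        return {
            "temperature_K": self.temperature,
            "kBT_pN_nm": self.kBT,
            "kBT_kcal_mol": self.kBT_kcal_mol,
            "kcal_per_mol_in_pN_nm": KCAL_PER_MOL_IN_PN_NM,
            "v_water_l_mol": self.v_water,
        }


@dataclass(frozen=True)
class WLCModel:
    """Worm-like-chain tether: persistence length and contour length in nm."""

    Lp: float
    Lc: float

    def __post_init__(self) -> None:
        if self.Lp <= 0:
            raise ValueError(f"persistence length must be > 0, got {self.Lp}")
        if self.Lc <= 0:
            raise ValueError(f"contour length must be > 0, got {self.Lc}")


@dataclass(frozen=True)
class BellModel:
    """Force-activated unbinding: rate ``k_ref`` at force ``F_ref`` (pN) with
    distance to the transition state ``x_t`` (nm)."""

    k_ref: float
    F_ref: float = 0.0
    x_t: float = 0.0

    def __post_init__(self) -> None:
        if self.k_ref <= 0:
            raise ValueError(f"k_ref must be > 0, got {self.k_ref}")
        if self.x_t < 0:
            raise ValueError(f"x_t must be >= 0, got {self.x_t}")


@dataclass(frozen=True)
class FNdYModel:
    """Friddle-Noy-de Yoreo bond model.

    Attributes
    ----------
    F_eq : float
        Equilibrium force (pN) at which unbinding and rebinding balance.
    f_beta : float
        Thermal force scale kBT/x_t (pN); slope of the kinetic branch per
        e-fold of loading rate.
    k_off_eq : float
        Unbinding rate at F_eq (1/s).
    k_eff : float
        Effective probe stiffness (pN/nm), the series stiffness of cantilever
        and tether at rupture; links F_eq to the binding free energy through
        deltaG_bu = -F_eq**2 / (2 k_eff).
    """

    F_eq: float
    f_beta: float
    k_off_eq: float
    k_eff: float = 13.1

    def __post_init__(self) -> None:
        if self.F_eq < 0:
            raise ValueError(f"F_eq must be >= 0, got {self.F_eq}")
        if self.f_beta <= 0:
            raise ValueError(f"f_beta must be > 0, got {self.f_beta}")
        if self.k_off_eq <= 0:
            raise ValueError(f"k_off_eq must be > 0, got {self.k_off_eq}")
        if self.k_eff <= 0:
            raise ValueError(f"k_eff must be > 0, got {self.k_eff}")

    @property
    def r0(self) -> float:
        """Thermal loading-rate scale r_0 = k_off_eq * f_beta (pN/s)."""
        return self.k_off_eq * self.f_beta


@dataclass
class ThermoResult:
    """Derived binding thermodynamics/kinetics with s.e.m. uncertainties.

    ``deltaG_bu`` in kcal/mol (negative = favourable), ``Kd`` in mol/l,
    ``tau_half`` in seconds.
    """

    deltaG_bu: float
    Kd: float
    tau_half: float
    deltaG_sem: float = float("nan")
    Kd_sem: float = float("nan")
    tau_half_sem: float = float("nan")
    label: str = ""
    constants: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "deltaG_bu_kcal_mol": self.deltaG_bu,
            "deltaG_sem_kcal_mol": self.deltaG_sem,
            "Kd_M": self.Kd,
            "Kd_sem_M": self.Kd_sem,
            "tau_half_s": self.tau_half,
            "tau_half_sem_s": self.tau_half_sem,
            "constants": dict(self.constants),
        }


def wlc_force(x, model: WLCModel, tc: ThermoConstants = ThermoConstants()):
    """Worm-like-chain force (pN) at extension ``x`` (nm).

    Uses the standard interpolation formula

        F(x) = (kBT/Lp) * [ 1/(4 (1 - x/Lc)^2) - 1/4 + x/Lc ]

    valid for 0 <= x < Lc; diverges as x -> Lc.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x >= model.Lc):
        raise ValueError(
            f"extension must satisfy 0 <= x < Lc={model.Lc} nm"
        )
    frac = x / model.Lc
    out = (tc.kBT / model.Lp) * (0.25 / (1.0 - frac) ** 2 - 0.25 + frac)
    return float(out) if out.ndim == 0 else out


def wlc_stiffness(x, model: WLCModel, tc: ThermoConstants = ThermoConstants()):
    """dF/dx (pN/nm) of the WLC interpolation formula at extension ``x`` nm."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x >= model.Lc):
        raise ValueError(f"extension must satisfy 0 <= x < Lc={model.Lc} nm")
    frac = x / model.Lc
    out = (tc.kBT / model.Lp) * (0.5 / (1.0 - frac) ** 3 + 1.0) / model.Lc
    return float(out) if out.ndim == 0 else out


def bell_off_rate(F, model: BellModel, tc: ThermoConstants = ThermoConstants()):
    """Bell unbinding rate k(F) = k_ref * exp(x_t (F - F_ref) / kBT) in 1/s."""
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("force must be finite")
    out = model.k_ref * np.exp(model.x_t * (F - model.F_ref) / tc.kBT)
    return float(out) if out.ndim == 0 else out


def fndy_mean_force(r, model: FNdYModel):
    """FNdY mean rupture force (pN) at loading rate ``r`` (pN/s).

        <F>(r) = F_eq + f_beta * ln(1 + exp(-gamma) * r / r_0)

    with r_0 = k_off_eq * f_beta and gamma the Euler-Mascheroni constant.
    The curve plateaus at F_eq for r << r_0 (bond rebinding keeps the probe
    near equilibrium) and grows log-linearly with slope f_beta for r >> r_0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("loading rate must be > 0 pN/s")
    out = model.F_eq + model.f_beta * np.log1p(
        math.exp(-EULER_GAMMA) * r / model.r0
    )
    return float(out) if out.ndim == 0 else out


def deltaG_from_Feq(
    F_eq: float, k_eff: float, tc: ThermoConstants = ThermoConstants()
) -> float:
    """Binding free energy (kcal/mol, <= 0) from the equilibrium force.

    deltaG_bu = -F_eq^2 / (2 k_eff), converted from pN*nm: the free energy
    stored in the effective probe spring when unbinding and rebinding rates
    balance.
    """
    if F_eq < 0:
        raise ValueError(f"F_eq must be >= 0, got {F_eq}")
    if k_eff <= 0:
        raise ValueError(f"k_eff must be > 0, got {k_eff}")
    return -(F_eq**2) / (2.0 * k_eff) / KCAL_PER_MOL_IN_PN_NM


def feq_from_deltaG(
    deltaG: float, k_eff: float, tc: ThermoConstants = ThermoConstants()
) -> float:
    """Equilibrium force (pN) implied by a binding free energy (kcal/mol)."""
    if deltaG > 0:
        raise ValueError(f"deltaG must be <= 0 kcal/mol, got {deltaG}")
    if k_eff <= 0:
        raise ValueError(f"k_eff must be > 0, got {k_eff}")
    return math.sqrt(-2.0 * k_eff * deltaG * KCAL_PER_MOL_IN_PN_NM)


def kd_from_deltaG(deltaG: float, tc: ThermoConstants = ThermoConstants()) -> float:
    """Dissociation constant (mol/l) from deltaG_bu (kcal/mol).

    Inverts deltaG_bu = kBT * ln(v_water * Kd), with v_water = 0.018 l/mol
    the partial molar volume of water.
    """
    if not math.isfinite(deltaG):
        raise ValueError("deltaG must be finite")
    return math.exp(deltaG / tc.kBT_kcal_mol) / tc.v_water


def deltaG_from_kd(Kd: float, tc: ThermoConstants = ThermoConstants()) -> float:
    """Forward relation deltaG_bu = kBT * ln(v_water * Kd), kcal/mol."""
    if Kd <= 0:
        raise ValueError(f"Kd must be > 0 M, got {Kd}")
    return tc.kBT_kcal_mol * math.log(tc.v_water * Kd)


def tau_half(k_off_eq: float) -> float:
    """Bond half-life tau_0.5 = ln 2 / k_off(F_eq) in seconds.

    The half-life of an exponentially distributed bound-state dwell at the
    equilibrium force — the most literal reading of a receptor-ligand
    residence half-life.
    """
    if k_off_eq <= 0:
        raise ValueError(f"k_off_eq must be > 0, got {k_off_eq}")
    return math.log(2.0) / k_off_eq
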