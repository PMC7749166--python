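"""Dynamic force spectroscopy inference.

Assembles specific rupture events into (loading rate, force) datasets, fits
the Friddle-Noy-de Yoreo mean-force model by Levenberg-Marquardt least
squares, derives binding thermodynamics (deltaG_bu, Kd, tau_0.5) with
first-order error propagation, and evaluates the two-site cooperativity
ledger (is the full-ligand binding free energy super-additive relative to
the individually measured sites?).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ConvergenceError, InsufficientDataError
from .physics import (
    EULER_GAMMA,
    FNdYModel,
    ThermoConstants,
    ThermoResult,
    deltaG_from_Feq,
    fndy_mean_force,
    kd_from_deltaG,
    tau_half,
)

__all__ = [
    "DFSDataset",
    "FNdYFit",
    "CooperativityLedger",
    "assemble_dfs",
    "fit_fndy",
    "bands",
    "derive_thermo",
    "estimate_k_eff",
    "cooperativity_ledger",
]

#: Default minimum number of events for a fit (configurable floor).
MIN_EVENTS = 30
#: Orientation gate: particles protruding less than this (nm) expose the
#: extracellular face to the probe.
ORIENTATION_HEIGHT_THRESHOLD = 1.75


@dataclass
class DFSDataset:
    """The (loading rate, force) cloud for one experimental condition."""

    loading_rates: np.ndarray
    forces: np.ndarray
    label: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        self.loading_rates = np.asarray(self.loading_rates, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.loading_rates.shape != self.forces.shape:
            raise ValueError("loading_rates and forces must match in shape")
        if np.any(self.loading_rates <= 0):
            raise ValueError("all loading rates must be > 0 pN/s")

    @property
    def n(self) -> int:
        return int(self.loading_rates.size)


@dataclass
class FNdYFit:
    """Fitted FNdY model with per-parameter s.e.m. and diagnostics."""

    model: FNdYModel
    sems: dict
    covar: np.ndarray | None
    n: int
    rms: float
    residual_var: float
    success: bool
    k_eff_policy: str = "fixed"
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "F_eq_pN": self.model.F_eq,
            "f_beta_pN": self.model.f_beta,
            "k_off_eq_per_s": self.model.k_off_eq,
            "k_eff_pN_nm": self.model.k_eff,
            "sems": dict(self.sems),
            "n": self.n,
            "rms_pN": self.rms,
            "k_eff_policy": self.k_eff_policy,
            "warnings": list(self.warnings),
        }


@dataclass
class CooperativityLedger:
    """Free-energy bookkeeping for a multi-site binding comparison.

    ``delta_delta_G = deltaG_full - sum(deltaG_parts)``; a negative value
    larger in magnitude than the propagated error indicates positive
    cooperativity (the intact ligand binds more favourably than its sites
    do independently).
    """

    deltaG_full: float
    deltaG_full_err: float
    deltaG_parts: list
    deltaG_parts_err: list
    deltaG_sum: float
    deltaG_sum_err: float
    delta_delta_G: float
    delta_delta_G_err: float
    verdict: str  # positive | none | negative

    def to_dict(self) -> dict:
        return {
            "deltaG_full_kcal_mol": self.deltaG_full,
            "deltaG_full_err": self.deltaG_full_err,
            "deltaG_parts_kcal_mol": list(self.deltaG_parts),
            "deltaG_parts_err": list(self.deltaG_parts_err),
            "deltaG_sum_kcal_mol": self.deltaG_sum,
            "deltaG_sum_err": self.deltaG_sum_err,
            "delta_delta_G_kcal_mol": self.delta_delta_G,
            "delta_delta_G_err": self.delta_delta_G_err,
            "verdict": self.verdict,
        }


def assemble_dfs(
    events: pd.DataFrame,
    condition: str = "",
    min_events: int = MIN_EVENTS,
    orientation_gate: bool = False,
    height_threshold: float = ORIENTATION_HEIGHT_THRESHOLD,
) -> DFSDataset:
    """Filter an event table to specific events and build a DFS dataset.

    One (LR, F) point per event, no binning. Force-volume and oscillatory
    runs merge naturally: each event carries its own measured loading rate.
    With ``orientation_gate`` set, only events recorded on particles whose
    protrusion height passes the extracellular-up criterion are kept.
    """
    sel = events["status"] == "specific"
    if orientation_gate:
        if "particle_height" not in events.columns:
            raise InsufficientDataError(
                "orientation gating requested but events carry no particle_height"
            )
        sel &= events["particle_height"] < height_threshold
    sub = events.loc[sel]
    lr = pd.to_numeric(sub["LR_pN_s"], errors="coerce")
    sub = sub[lr.notna() & (lr > 0)]
    if len(sub) < min_events:
        raise InsufficientDataError(
            f"{len(sub)} specific events for condition {condition!r} "
            f"(floor {min_events})"
        )
    return DFSDataset(
        loading_rates=sub["LR_pN_s"].to_numpy(),
        forces=sub["F_adh_pN"].to_numpy(),
        label=condition,
        provenance="event_table",
    )


def estimate_k_eff(loading_rates, velocities) -> float:
    """Effective probe stiffness (pN/nm) from per-event LR/velocity ratios.

    On a constant-velocity ramp the loading rate equals k_eff * v, so the
    median ratio estimates the series stiffness of cantilever and tether at
    rupture. Useful when the events carry their retract velocities.
    """
    loading_rates = np.asarray(loading_rates, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    ok = (loading_rates > 0) & (velocities > 0)
    if not np.any(ok):
        raise InsufficientDataError("no usable (LR, velocity) pairs")
    return float(np.median(loading_rates[ok] / velocities[ok]))


def _start_values(ds: DFSDataset) -> tuple[float, float, float]:
    """Deterministic initialization: F_eq from the 5th force percentile,
    f_beta from the semi-log slope over the upper LR decade, k_off 10^3/s."""
    f_eq0 = max(1.0, float(np.percentile(ds.forces, 5)))
    top = ds.loading_rates >= ds.loading_rates.max() / 10.0
    if top.sum() >= 3 and np.ptp(np.log(ds.loading_rates[top])) > 0:
        slope = np.polyfit(np.log(ds.loading_rates[top]), ds.forces[top], 1)[0]
        f_beta0 = float(np.clip(slope, 1.0, 100.0))
    else:
        f_beta0 = 10.0
    return f_eq0, f_beta0, 1e3


def fit_fndy(
    ds: DFSDataset,
    tc: ThermoConstants = ThermoConstants(),
    k_eff: float = 13.1,
    k_eff_policy: str = "fixed",
    min_events: int = MIN_EVENTS,
    binned: bool = False,
    n_bins: int = 15,
) -> FNdYFit:
    """Levenberg-Marquardt fit of the FNdY mean-force curve to a DFS cloud.

    Default objective: unweighted least squares of per-event forces against
    the model evaluated at each event's loading rate (per-event points, one
    fit line; no binning). A ``binned`` mode fitting log-LR bin means is
    provided for comparison. Parameter s.e.m. come from the covariance at
    the optimum. ``k_eff`` does not enter the mean-force curve; it is
    attached to the fitted model according to ``k_eff_policy`` for the
    downstream free-energy derivation.
    """
    if ds.n < min_events:
        raise InsufficientDataError(f"{ds.n} events < floor {min_events}")
    lr, f = ds.loading_rates, ds.forces
    warn: list[str] = []
    span = np.log10(lr.max() / lr.min()) if lr.min() > 0 else 0.0
    if span < 2.0:
        warn.append(
            f"loading-rate span {span:.2f} decades < 2; "
            "f_beta and k_off_eq may be poorly identified"
        )
    if binned:
        edges = np.logspace(np.log10(lr.min()), np.log10(lr.max()), n_bins + 1)
        idx = np.clip(np.digitize(lr, edges) - 1, 0, n_bins - 1)
        lr_fit, f_fit = [], []
        for b in range(n_bins):
            m = idx == b
            if m.sum() > 0:
                lr_fit.append(np.exp(np.mean(np.log(lr[m]))))
                f_fit.append(np.mean(f[m]))
        lr_fit, f_fit = np.asarray(lr_fit), np.asarray(f_fit)
    else:
        lr_fit, f_fit = lr, f

    f_eq0, f_beta0, k_off0 = _start_values(ds)
    params = lmfit.Parameters()
    params.add("F_eq", value=f_eq0, min=0.0, max=1e4)
    params.add("f_beta", value=f_beta0, min=1e-3, max=1e3)
    params.add("k_off_eq", value=k_off0, min=1e-9, max=1e12)

    def residual(p):
        model = FNdYModel(
            p["F_eq"].value, p["f_beta"].value, p["k_off_eq"].value, k_eff
        )
        return fndy_mean_force(lr_fit, model) - f_fit

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise ConvergenceError(
            f"FNdY fit did not converge: {result.message}", last_iterate=result
        )
    p = result.params
    model = FNdYModel(
        F_eq=float(p["F_eq"].value),
        f_beta=float(p["f_beta"].value),
        k_off_eq=float(p["k_off_eq"].value),
        k_eff=float(k_eff),
    )
    sems = {
        name: (float(p[name].stderr) if p[name].stderr is not None else float("nan"))
        for name in ("F_eq", "f_beta", "k_off_eq")
    }
    covar = getattr(result, "covar", None)
    if covar is None:
        warn.append("singular covariance at the optimum; s.e.m. unavailable")
    else:
        cond = float(np.linalg.cond(covar))
        if cond > 1e12:
            warn.append(f"ill-conditioned covariance (cond={cond:.2e})")
    resid_all = fndy_mean_force(lr, model) - f
    dof = max(1, lr.size - 3)
    return FNdYFit(
        model=model,
        sems=sems,
        covar=covar,
        n=ds.n,
        rms=float(np.sqrt(np.mean(resid_all**2))),
        residual_var=float(np.sum(resid_all**2) / dof),
        success=True,
        k_eff_policy=k_eff_policy,
        warnings=warn,
    )


def _gradient(model: FNdYModel, lr: np.ndarray) -> np.ndarray:
    """Analytic gradient of the mean force wrt (F_eq, f_beta, k_off_eq)."""
    u = np.exp(-EULER_GAMMA) * lr / (model.k_off_eq * model.f_beta)
    g = np.empty((lr.size, 3))
    g[:, 0] = 1.0
    g[:, 1] = np.log1p(u) - u / (1.0 + u)
    g[:, 2] = -model.f_beta * u / ((1.0 + u) * model.k_off_eq)
    return g


def bands(
    fit: FNdYFit, lr_grid, level: float = 0.99
) -> pd.DataFrame:
    """Confidence and prediction bands of the fitted mean-force curve.

    CI: first-order propagation of the parameter covariance through the
    model (delta method). PI: CI variance plus the residual scatter, so the
    PI should cover ~``level`` of fresh points. Bands widen away from the
    data's centre of mass in ln(LR).
    """
    if fit.covar is None:
        raise ConvergenceError("covariance unavailable; bands cannot be computed")
    lr_grid = np.asarray(lr_grid, dtype=float)
    mean = fndy_mean_force(lr_grid, fit.model)
    g = _gradient(fit.model, lr_grid)
    var_ci = np.einsum("ij,jk,ik->i", g, fit.covar, g)
    var_ci = np.maximum(var_ci, 0.0)
    z = norm.ppf(0.5 + level / 2.0)
    half_ci = z * np.sqrt(var_ci)
    half_pi = z * np.sqrt(var_ci + fit.residual_var)
    return pd.DataFrame(
        {
            "LR_pN_s": lr_grid,
            "mean_pN": mean,
            "ci_lo_pN": mean - half_ci,
            "ci_hi_pN": mean + half_ci,
            "pi_lo_pN": mean - half_pi,
            "pi_hi_pN": mean + half_pi,
        }
    )


def derive_thermo(
    fit: FNdYFit, tc: ThermoConstants = ThermoConstants(), label: str = ""
) -> ThermoResult:
    """Binding thermodynamics from a converged FNdY fit.

    deltaG_bu = -F_eq^2/(2 k_eff); Kd from the water-volume relation;
    tau_0.5 = ln2/k_off_eq. Uncertainties are first-order propagations of
    the parameter s.e.m. (sigma_deltaG = F_eq*sigma_F/k_eff, i.e.
    2|deltaG|*sigma_F/F_eq).
    """
    m = fit.model
    dG = deltaG_from_Feq(m.F_eq, m.k_eff, tc)
    kd = kd_from_deltaG(dG, tc)
    th = tau_half(m.k_off_eq)
    sF = fit.sems.get("F_eq", float("nan"))
    sk = fit.sems.get("k_off_eq", float("nan"))
    dG_sem = abs(2.0 * dG * sF / m.F_eq) if m.F_eq > 0 else float("nan")
    kd_sem = kd * dG_sem / tc.kBT_kcal_mol
    th_sem = th * sk / m.k_off_eq
    return ThermoResult(
        deltaG_bu=dG,
        Kd=kd,
        tau_half=th,
        deltaG_sem=dG_sem,
        Kd_sem=kd_sem,
        tau_half_sem=th_sem,
        label=label,
        constants=tc.to_dict(),
    )


def cooperativity_ledger(full: ThermoResult, parts) -> CooperativityLedger:
    """Compare the full-ligand free energy with the sum of its sites.

    ``delta_delta_G < 0`` beyond the quadrature-propagated error means the
    intact ligand binds more favourably than the independent sum: positive
    cooperativity between the sites.
    """
    parts = list(parts)
    if len(parts) < 2:
        raise ValueError("cooperativity ledger needs >= 2 individually measured sites")
    part_g = [p.deltaG_bu for p in parts]
    part_e = [p.deltaG_sem for p in parts]
    g_sum = float(np.sum(part_g))
    e_sum = float(np.sqrt(np.nansum(np.square(part_e))))
    ddg = full.deltaG_bu - g_sum
    ddg_err = float(np.sqrt(np.nansum([full.deltaG_sem**2, e_sum**2])))
    if ddg < 0 and abs(ddg) > ddg_err:
        verdict = "positive"
    elif ddg > ddg_err:
        verdict = "negative"
    else:
        verdict = "none"
    return CooperativityLedger(
        deltaG_full=full.deltaG_bu,
        deltaG_full_err=full.deltaG_sem,
        deltaG_parts=part_g,
        deltaG_parts_err=part_e,
        deltaG_sum=g_sum,
        deltaG_sum_err=e_sum,
        delta_delta_G=ddg,
        delta_delta_G_err=ddg_err,
        verdict=verdict,
    )
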