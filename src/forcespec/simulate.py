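"""Synthetic data generation with recorded ground truth.

Emulates the instrument for every pipeline input:

* force-distance cycles with stochastic bond rupture — a two-state
  (bound/unbound) Gillespie process under the time-varying force imposed by
  a WLC tether in series with the cantilever, driven by a linear ramp
  (force-volume mode) or a sinusoidal oscillation;
* fast-path dynamic-force-spectroscopy event ensembles;
* bilayer height maps with particle populations of known heights/diameters.

Kinetics: unbinding follows ``k_off(F) = k_off_eq * exp((F - F_eq)/f_beta)``;
rebinding follows the detailed-balance construction against the harmonic
probe potential, ``k_on(F) = k_off_eq * exp((F_eq^2 - F^2)/(2 k_eff kBT))``,
which makes the two rates balance exactly at F_eq — the equilibrium condition
the FNdY model is built on. All generators are reproducible given
(seed, config) and emit truth records sufficient to score every downstream
stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import FDCurve
from .dfs import DFSDataset
from .exceptions import PlacementError
from .physics import (
    FNdYModel,
    ThermoConstants,
    WLCModel,
    fndy_mean_force,
    wlc_force,
    wlc_stiffness,
)

__all__ = [
    "LoadingProtocol",
    "BondTruth",
    "MapTruth",
    "gen_fd_curve",
    "gen_fd_curves",
    "simulate_rupture_forces",
    "gen_dfs_dataset",
    "gen_height_map",
    "gen_multiplex_events",
    "write_manifest",
]

_EXP_CLIP = 700.0  # exp() argument clip against overflow


@dataclass(frozen=True)
class LoadingProtocol:
    """Tip-drive protocol of one approach/retract cycle.

    Defaults follow force-volume practice: 1 um/s approach, 1 um/s retract
    (0.5-2 um/s range), 150 nm ramp; the oscillatory mode runs at 250 Hz
    with 100 nm peak-to-peak amplitude.
    """

    kind: str = "linear_ramp"  # linear_ramp | sinusoidal
    approach_velocity: float = 1000.0  # nm/s
    retract_velocity: float = 1000.0  # nm/s
    ramp_size: float = 150.0  # nm
    frequency: float = 250.0  # Hz, sinusoidal mode
    amplitude: float = 100.0  # nm peak-to-peak, sinusoidal mode
    samples_per_segment: int = 2000

    def __post_init__(self) -> None:
        if self.kind not in ("linear_ramp", "sinusoidal"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if min(
            self.approach_velocity,
            self.retract_velocity,
            self.ramp_size,
            self.frequency,
            self.amplitude,
        ) <= 0:
            raise ValueError("protocol velocities/frequency/amplitude must be > 0")

    def retract_heights_times(self) -> tuple[np.ndarray, np.ndarray]:
        """(piezo height above contact, time) samples of the retract."""
        n = self.samples_per_segment
        if self.kind == "linear_ramp":
            t = np.linspace(0.0, self.ramp_size / self.retract_velocity, n)
            h = self.retract_velocity * t
        else:
            half_period = 0.5 / self.frequency
            t = np.linspace(0.0, half_period, n)
            h = 0.5 * self.amplitude * (1.0 - np.cos(2.0 * np.pi * self.frequency * t))
        return h, t

    def approach_heights_times(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.samples_per_segment
        if self.kind == "linear_ramp":
            t = np.linspace(0.0, self.ramp_size / self.approach_velocity, n)
            h = self.ramp_size - self.approach_velocity * t
        else:
            half_period = 0.5 / self.frequency
            t = np.linspace(0.0, half_period, n)
            h = 0.5 * self.amplitude * (1.0 + np.cos(2.0 * np.pi * self.frequency * t))
        return h, t


@dataclass(frozen=True)
class BondTruth:
    """Ground-truth bond parameters driving the stochastic simulator."""

    model: FNdYModel = FNdYModel(F_eq=50.0, f_beta=10.0, k_off_eq=1e3, k_eff=13.1)
    tether: WLCModel = WLCModel(Lp=0.38, Lc=10.0)
    binding_probability: float = 0.2
    rebinding: bool = True
    cantilever_k: float = 100.0  # pN/nm (0.1 N/m class levers)


@dataclass(frozen=True)
class MapTruth:
    """Ground-truth particle populations for synthetic height maps.

    Height populations (nm): 1.1 +/- 0.5 (extracellular face up) and
    2.8 +/- 1.2 (intracellular face up). Diameter populations (FWHM, nm):
    8.6 +/- 0.4, 14.1 +/- 0.3, 23.4 +/- 1.2 (monomer, dimer, oligomer).
    """

    n_particles: int = 60
    height_means: tuple = (1.1, 2.8)
    height_sds: tuple = (0.5, 1.2)
    height_weights: tuple = (0.5, 0.5)
    diam_means: tuple = (8.6, 14.1, 23.4)
    diam_sds: tuple = (0.4, 0.3, 1.2)
    diam_weights: tuple = (0.5, 0.3, 0.2)
    roughness_sd: float = 0.06  # nm
    pixel_size: float = 2.0  # nm/px
    tilt: tuple = (0.0, 0.0)  # nm per px along rows/cols
    min_height: float = 0.2  # nm, truncation floor for drawn heights


def _hazards(F, truth: BondTruth, tc: ThermoConstants):
    """(k_off, k_on) in 1/s at bond force F (pN); F is the force the bond
    carries (or would carry) at the current probe position."""
    m = truth.model
    F = np.asarray(F, dtype=float)
    log_k0 = np.log(m.k_off_eq)
    k_off = np.exp(np.clip(log_k0 + (F - m.F_eq) / m.f_beta, -_EXP_CLIP, _EXP_CLIP))
    if truth.rebinding:
        arg = (m.F_eq**2 - F**2) / (2.0 * m.k_eff * tc.kBT)
        k_on = np.exp(np.clip(log_k0 + arg, -_EXP_CLIP, _EXP_CLIP))
    else:
        k_on = np.zeros_like(k_off)
    return k_off, k_on


def _solve_extension(h, tether: WLCModel, k_c: float, tc: ThermoConstants):
    """Tether extension x at piezo height h: x + F_wlc(x)/k_c = h (bisection).

    Heights beyond where the WLC force reaches an extreme load are clamped to
    just under the contour length; the bond never survives there.
    """
    h = np.asarray(h, dtype=float)
    lo = np.zeros_like(h)
    hi = np.full_like(h, tether.Lc * (1.0 - 1e-9))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        g = mid + wlc_force(mid, tether, tc) / k_c - h
        too_high = g > 0
        hi = np.where(too_high, mid, hi)
        lo = np.where(too_high, lo, mid)
    return 0.5 * (lo + hi)


def _first_event_index(cum_hazard: np.ndarray, start: int, u: float) -> int:
    """First sample index >= start where the integrated hazard (cumulative,
    per-sample) exceeds the exponential draw -ln u; len(cum) if never."""
    target = -np.log(u) + (cum_hazard[start - 1] if start > 0 else 0.0)
    idx = int(np.searchsorted(cum_hazard, target, side="left"))
    return idx


def gen_fd_curve(
    protocol: LoadingProtocol,
    truth: BondTruth,
    noise_sigma: float = 12.0,
    seed: int | np.random.Generator = 0,
    tc: ThermoConstants = ThermoConstants(),
    force_bind: bool | None = None,
    curve_id: str = "",
    pixel: tuple[int, int] = (-1, -1),
) -> tuple[FDCurve, dict]:
    """One synthetic approach/retract cycle plus its ground-truth record.

    While bound the recorded force is the WLC tether load transmitted through
    the cantilever (quasi-static series response); unbound samples sit on the
    zero baseline. Gaussian force noise of SD ``noise_sigma`` is added to the
    whole record. The truth record carries the bond state at contact and, if
    the bond ruptured, the final unbinding (force, separation, time, and the
    instantaneous loading rate of the noiseless signal just before rupture,
    mirroring the measurement definition).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h_app, t_app = protocol.approach_heights_times()
    h_ret, t_ret = protocol.retract_heights_times()
    n = h_ret.size
    dt = np.gradient(t_ret)

    if force_bind is None:
        bound0 = bool(rng.random() < truth.binding_probability)
    else:
        bound0 = bool(force_bind)

    F_bond = np.zeros(n)
    rupture = None
    if bound0:
        x = _solve_extension(h_ret, truth.tether, truth.cantilever_k, tc)
        F_if_bound = wlc_force(
            np.minimum(x, truth.tether.Lc * (1 - 1e-9)), truth.tether, tc
        )
        k_off, k_on = _hazards(F_if_bound, truth, tc)
        cum_off = np.cumsum(k_off * dt)
        cum_on = np.cumsum(k_on * dt)
        bound = np.zeros(n, dtype=bool)
        i, state = 0, True
        last_unbind = None
        while i < n:
            if state:
                j = _first_event_index(cum_off, i, rng.random())
                bound[i : min(j + 1, n)] = True
                if j >= n:
                    break
                last_unbind = j
                state = False
                i = j + 1
            else:
                j = _first_event_index(cum_on, i, rng.random())
                if j >= n:
                    break
                state = True
                i = j
        F_bond = np.where(bound, F_if_bound, 0.0)
        if last_unbind is not None and not state:
            j = last_unbind
            # loading rate of the noiseless force just before rupture
            k = max(2, min(10, j))
            if j >= 2:
                lr = float(np.polyfit(t_ret[j - k : j + 1], F_if_bound[j - k : j + 1], 1)[0])
            else:
                lr = float("nan")
            rupture = {
                "force_pN": float(F_if_bound[j]),
                "separation_nm": float(x[j]),
                "time_s": float(t_ret[j]),
                "loading_rate_pN_s": lr,
            }

    # the bound tip sits at the tether extension, not the piezo height
    z_ret = np.where(F_bond > 0, x, h_ret) if bound0 else h_ret.copy()
    F_ret = -F_bond
    F_app = np.zeros_like(h_app)
    z_app = h_app

    t = np.concatenate([t_app, t_app[-1] + dt[0] + t_ret])
    z = np.concatenate([z_app, z_ret])
    F = np.concatenate([F_app, F_ret])
    if noise_sigma > 0:
        F = F + rng.normal(0.0, noise_sigma, size=F.size)

    meta = {
        "curve_id": curve_id,
        "pixel": pixel,
        "mode": "FV" if protocol.kind == "linear_ramp" else "oscillatory",
        "frequency_Hz": protocol.frequency,
        "amplitude_nm": protocol.amplitude,
        "retract_velocity_nm_s": protocol.retract_velocity,
        "spring_constant_pN_nm": truth.cantilever_k,
        "noise_sigma_pN": noise_sigma,
    }
    curve = FDCurve(t=t, z=z, F=F, meta=meta, split_index=h_app.size)
    truth_rec = {
        "curve_id": curve_id,
        "bound_at_contact": bound0,
        "rupture": rupture,
    }
    return curve, truth_rec


def gen_fd_curves(
    n: int,
    protocol: LoadingProtocol,
    truth: BondTruth,
    noise_sigma: float = 12.0,
    seed: int = 0,
    tc: ThermoConstants = ThermoConstants(),
    force_bind: bool | None = None,
) -> tuple[list[FDCurve], list[dict]]:
    """Batch of cycles with independent child seeds from one parent seed."""
    rng = np.random.default_rng(seed)
    curves, truths = [], []
    for i in range(n):
        c, tr = gen_fd_curve(
            protocol,
            truth,
            noise_sigma=noise_sigma,
            seed=rng,
            tc=tc,
            force_bind=force_bind,
            curve_id=f"sim-{seed}-{i:05d}",
            pixel=(i, 0),
        )
        curves.append(c)
        truths.append(tr)
    return curves, truths


def simulate_rupture_forces(
    loading_rate: float,
    truth: BondTruth,
    n: int = 10_000,
    seed: int = 0,
    tc: ThermoConstants = ThermoConstants(),
    dF: float = 0.1,
    f_max: float | None = None,
) -> np.ndarray:
    """Final-unbinding forces of the two-state bond under a constant force
    ramp ``F(t) = r t`` — the module's core oracle against the FNdY mean.

    Vectorized over ``n`` replicates: the force axis is discretized in ``dF``
    steps; within each step the hazards are constants evaluated at the
    midpoint force, so per-step transition probabilities 1-exp(-k dt) are
    exact. The recorded rupture is the final unbinding after which rebinding
    never re-occurs (the ramp ends far above F_eq where rebinding is
    suppressed by the probe-spring energy, so late rebinds are negligible).
    """
    if loading_rate <= 0:
        raise ValueError("loading rate must be > 0")
    m = truth.model
    if f_max is None:
        f_max = m.F_eq + 12.0 * m.f_beta
    rng = np.random.default_rng(seed)
    grid = np.arange(0.0, f_max, dF)
    mid = grid + 0.5 * dF
    k_off, k_on = _hazards(mid, truth, tc)
    dt = dF / loading_rate
    p_off = -np.expm1(-k_off * dt)
    p_on = -np.expm1(-k_on * dt)

    bound = np.ones(n, dtype=bool)
    last_rupture = np.full(n, np.nan)
    for k in range(grid.size):
        u = rng.random(n)
        unbinds = bound & (u < p_off[k])
        rebinds = (~bound) & (u < p_on[k])
        last_rupture[unbinds] = mid[k]
        bound = (bound & ~unbinds) | rebinds
    # any replicate still bound at f_max ruptures there (k_off is enormous)
    last_rupture[bound] = f_max
    return last_rupture


def gen_dfs_dataset(
    n: int,
    truth: BondTruth,
    lr_range: tuple[float, float] = (1e2, 1e6),
    scatter_sd: float = 10.0,
    seed: int = 0,
    tc: ThermoConstants = ThermoConstants(),
    mode: str = "gaussian",
    label: str = "synthetic",
) -> tuple[DFSDataset, dict]:
    """Fast-path DFS ensemble: n (LR, F) points with known truth.

    Loading rates are log-uniform over ``lr_range``. In ``gaussian`` mode the
    forces are the FNdY mean at each LR plus Gaussian scatter of SD
    ``scatter_sd`` (the desk-scale emulation of per-event spread); in
    ``gillespie`` mode they are drawn from the stochastic two-state simulator
    at each LR (slower, distributionally faithful).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lr = np.exp(rng.uniform(np.log(lr_range[0]), np.log(lr_range[1]), size=n))
    if mode == "gaussian":
        f = fndy_mean_force(lr, truth.model)
        if scatter_sd > 0:
            f = f + rng.normal(0.0, scatter_sd, size=n)
    elif mode == "gillespie":
        f = np.array(
            [
                simulate_rupture_forces(
                    r, truth, n=1, seed=int(rng.integers(2**31)), tc=tc
                )[0]
                for r in lr
            ]
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ds = DFSDataset(loading_rates=lr, forces=f, label=label, provenance=f"sim:{mode}")
    truth_rec = {
        "F_eq_pN": truth.model.F_eq,
        "f_beta_pN": truth.model.f_beta,
        "k_off_eq_per_s": truth.model.k_off_eq,
        "k_eff_pN_nm": truth.model.k_eff,
        "scatter_sd_pN": scatter_sd,
        "lr_range_pN_s": list(lr_range),
        "mode": mode,
        "seed": seed if not isinstance(seed, np.random.Generator) else None,
    }
    return ds, truth_rec


def gen_height_map(
    truth: MapTruth,
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Synthetic bilayer height map (nm) plus the planted-particle table.

    Particles are isotropic Gaussian bumps: height drawn from the two-peak
    height mixture (the component is the orientation ground truth), FWHM from
    the three-peak diameter mixture. Centers are placed by rejection sampling
    with a non-overlap margin; correlated sub-pixel roughness and an optional
    plane tilt are added. Truth table columns:
    (id, row, col, height_nm, fwhm_nm, orientation).
    """
    rng = np.random.default_rng(seed)
    rows, cols = size
    grid = np.zeros((rows, cols))
    px = truth.pixel_size

    comp = rng.choice(len(truth.height_means), size=truth.n_particles,
                      p=np.asarray(truth.height_weights) / np.sum(truth.height_weights))
    heights = np.empty(truth.n_particles)
    for i, c in enumerate(comp):
        h = rng.normal(truth.height_means[c], truth.height_sds[c])
        while h < truth.min_height:
            h = rng.normal(truth.height_means[c], truth.height_sds[c])
        heights[i] = h
    dcomp = rng.choice(len(truth.diam_means), size=truth.n_particles,
                       p=np.asarray(truth.diam_weights) / np.sum(truth.diam_weights))
    fwhms = np.maximum(
        2.0 * px, rng.normal(np.take(truth.diam_means, dcomp), np.take(truth.diam_sds, dcomp))
    )

    centers = []
    margin_px = fwhms / px  # keep ~1 FWHM of clearance around each particle
    max_tries = 200 * max(1, truth.n_particles)
    tries = 0
    for i in range(truth.n_particles):
        placed = False
        while tries < max_tries:
            tries += 1
            r = rng.uniform(2 * margin_px[i], rows - 1 - 2 * margin_px[i])
            c = rng.uniform(2 * margin_px[i], cols - 1 - 2 * margin_px[i])
            ok = all(
                np.hypot(r - r0, c - c0) > (margin_px[i] + m0)
                for (r0, c0, m0) in centers
            )
            if ok:
                centers.append((r, c, margin_px[i]))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place particle {i} of {truth.n_particles} "
                f"without overlap in a {rows}x{cols} field"
            )

    rr, cc = np.mgrid[0:rows, 0:cols]
    records = []
    for i, (r0, c0, _) in enumerate(centers):
        sigma_px = fwhms[i] / 2.354820045 / px
        bump = heights[i] * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma_px**2)
        )
        grid += bump
        records.append(
            {
                "id": i,
                "row": r0,
                "col": c0,
                "height_nm": heights[i],
                "fwhm_nm": fwhms[i],
                "orientation": "extracellular_up" if comp[i] == 0 else "intracellular_up",
            }
        )

    if truth.roughness_sd > 0:
        from scipy.ndimage import gaussian_filter

        white = rng.normal(0.0, 1.0, size=(rows, cols))
        rough = gaussian_filter(white, sigma=0.8)
        rough *= truth.roughness_sd / max(rough.std(), 1e-12)
        grid += rough
    if any(truth.tilt):
        grid += truth.tilt[0] * rr + truth.tilt[1] * cc

    return grid, pd.DataFrame.from_records(records)


def gen_multiplex_events(
    particle_truth: pd.DataFrame,
    consistency: float = 0.95,
    seed: int = 0,
    threshold: float = 1.75,
) -> dict[str, list[tuple[int, int]]]:
    """Per-probe specific-event pixels for the multiplex overlay check.

    With probability ``consistency`` a particle binds the probe matching its
    orientation (ligand probe for extracellular-up, his-tag probe for
    intracellular-up); otherwise the other probe.
    """
    rng = np.random.default_rng(seed)
    events = {"ligand": [], "his_tag": []}
    for _, p in particle_truth.iterrows():
        matching = "ligand" if p["orientation"] == "extracellular_up" else "his_tag"
        other = "his_tag" if matching == "ligand" else "ligand"
        probe = matching if rng.random() < consistency else other
        events[probe].append((int(round(p["row"])), int(round(p["col"]))))
    return events


def write_manifest(path, entries: dict) -> None:
    """Record generated files and their seeds/configs alongside a dataset."""
    Path(path).write_text(json.dumps(entries, indent=1, default=str))
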