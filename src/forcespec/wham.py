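"""Desk-scale umbrella sampling and a from-scratch WHAM solver.

A 1-D overdamped Langevin sampler on analytic model potentials stands in for
the all-atom pulling system: harmonically biased windows along a reaction
coordinate are sampled, the unbiased potential of mean force (PMF) is
recovered by self-consistent WHAM iteration, statistical errors come from a
block bootstrap, and the binding free energy / barrier height are read off
the profile.

Energies are in kcal/mol, the reaction coordinate in nm, bias constants in
kcal/mol/nm^2 (the conventional 1000 kJ/mol/nm^2 umbrella constant is
~239 kcal/mol/nm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    ConvergenceError,
    NoBoundStateError,
    WindowOverlapError,
)
from .physics import ThermoConstants

__all__ = [
    "ModelPotential",
    "UmbrellaWindow",
    "PMFProfile",
    "KCAL_MOL_NM2_PER_KJ_MOL_NM2",
    "default_windows",
    "simulate_umbrella",
    "wham",
    "bootstrap_pmf",
    "deltaG_and_barrier",
]

KCAL_MOL_NM2_PER_KJ_MOL_NM2 = 1.0 / 4.184
#: The conventional all-atom umbrella constant, 1000 kJ/mol/nm^2.
PAPER_PARITY_BIAS_K = 1000.0 * KCAL_MOL_NM2_PER_KJ_MOL_NM2
#: Default bias for the desk-scale sampler: chosen so the biased fluctuation
#: sqrt(kBT/k_w) ~ 0.1 nm matches the window spacing, giving strong adjacent
#: histogram overlap at desk-scale sample counts.
DEFAULT_BIAS_K = 59.0
#: Conventional window count for a full dissociation path.
DEFAULT_N_WINDOWS = 36


@dataclass(frozen=True)
class ModelPotential:
    """Analytic 1-D potential with known extrema (the truth source).

    Use the factory classmethods; ``energy`` and ``grad`` evaluate U(xi) in
    kcal/mol and dU/dxi in kcal/mol/nm.
    """

    kind: str
    params: dict = field(default_factory=dict)

    @classmethod
    def double_well(
        cls,
        well_depth: float,
        barrier: float,
        well_pos: float = 1.0,
        barrier_pos: float = 2.2,
        well_width: float = 0.35,
        barrier_width: float = 0.25,
    ) -> "ModelPotential":
        """Bound well of depth ``well_depth`` below the unbound plateau (0)
        and a barrier ``barrier`` above the well, built from two Gaussians
        far enough apart that the nominal extrema hold to ~0.005 kcal/mol."""
        if well_depth <= 0 or barrier <= 0:
            raise ValueError("well depth and barrier must be > 0 kcal/mol")
        if barrier < well_depth:
            raise ValueError(
                "barrier is measured from the well and cannot be below the "
                "plateau: need barrier >= well_depth"
            )
        return cls(
            kind="double_well",
            params={
                "D": float(well_depth),
                "B": float(barrier),
                "x_well": float(well_pos),
                "x_barrier": float(barrier_pos),
                "w_well": float(well_width),
                "w_barrier": float(barrier_width),
            },
        )

    @classmethod
    def harmonic(cls, k: float, center: float = 0.0) -> "ModelPotential":
        return cls(kind="harmonic", params={"k": float(k), "center": float(center)})

    @classmethod
    def morse_like(cls, depth: float, a: float = 3.0, x0: float = 1.0) -> "ModelPotential":
        """Single well of ``depth`` rising monotonically to a plateau at 0."""
        return cls(kind="morse_like", params={"D": float(depth), "a": float(a), "x0": float(x0)})

    @classmethod
    def tabulated(cls, xi, u) -> "ModelPotential":
        from scipy.interpolate import CubicSpline

        spline = CubicSpline(np.asarray(xi, float), np.asarray(u, float))
        return cls(kind="tabulated", params={"spline": spline})

    def energy(self, xi):
        xi = np.asarray(xi, dtype=float)
        p = self.params
        if self.kind == "double_well":
            out = -p["D"] * np.exp(-((xi - p["x_well"]) ** 2) / (2 * p["w_well"] ** 2)) + (
                p["B"] - p["D"]
            ) * np.exp(-((xi - p["x_barrier"]) ** 2) / (2 * p["w_barrier"] ** 2))
        elif self.kind == "harmonic":
            out = 0.5 * p["k"] * (xi - p["center"]) ** 2
        elif self.kind == "morse_like":
            out = p["D"] * ((1.0 - np.exp(-p["a"] * (xi - p["x0"]))) ** 2 - 1.0)
        elif self.kind == "tabulated":
            out = p["spline"](xi)
        else:
            raise ValueError(f"unknown potential kind {self.kind!r}")
        return float(out) if out.ndim == 0 else out

    def grad(self, xi):
        xi = np.asarray(xi, dtype=float)
        p = self.params
        if self.kind == "double_well":
            g1 = (
                p["D"]
                * (xi - p["x_well"])
                / p["w_well"] ** 2
                * np.exp(-((xi - p["x_well"]) ** 2) / (2 * p["w_well"] ** 2))
            )
            g2 = (
                -(p["B"] - p["D"])
                * (xi - p["x_barrier"])
                / p["w_barrier"] ** 2
                * np.exp(-((xi - p["x_barrier"]) ** 2) / (2 * p["w_barrier"] ** 2))
            )
            out = g1 + g2
        elif self.kind == "harmonic":
            out = p["k"] * (xi - p["center"])
        elif self.kind == "morse_like":
            e = np.exp(-p["a"] * (xi - p["x0"]))
            out = 2.0 * p["D"] * p["a"] * e * (1.0 - e)
        elif self.kind == "tabulated":
            out = p["spline"](xi, 1)
        else:
            raise ValueError(f"unknown potential kind {self.kind!r}")
        return float(out) if out.ndim == 0 else out


@dataclass
class UmbrellaWindow:
    """One biased window: harmonic restraint at ``center`` with spring
    ``k_w`` (kcal/mol/nm^2) and post-equilibration samples of xi (nm)."""

    center: float
    k_w: float
    samples: np.ndarray
    n_equilibration: int = 0

    def __post_init__(self) -> None:
        if self.k_w <= 0:
            raise ValueError("bias spring constant must be > 0")
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class PMFProfile:
    """Free energy vs reaction coordinate, minimum set to zero."""

    xi: np.ndarray
    G: np.ndarray
    sd: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)


def default_windows(
    lo: float = 0.4, hi: float = 3.9, n: int = DEFAULT_N_WINDOWS
) -> np.ndarray:
    """Evenly spaced window centers spanning the dissociation coordinate."""
    return np.linspace(lo, hi, n)


def simulate_umbrella(
    pot: ModelPotential,
    centers,
    k_w: float = DEFAULT_BIAS_K,
    n_samples: int = 10_000,
    n_equilibration: int = 500,
    dt: float = 5e-4,
    friction: float = 1.0,
    thin: int = 10,
    tc: ThermoConstants = ThermoConstants(),
    seed: int = 0,
) -> list[UmbrellaWindow]:
    """Overdamped Langevin sampling of every biased window (vectorized).

    Euler-Maruyama step: dxi = -(U' + k_w (xi - c))/friction dt
    + sqrt(2 kBT dt / friction) eta. The step size must satisfy
    dt * k_total / friction < 0.1 for stability (checked against the bias
    plus the numerically estimated maximum potential curvature).
    """
    centers = np.asarray(centers, dtype=float)
    kBT = tc.kBT_kcal_mol
    # curvature estimate over the sampled range for the stability criterion
    span = np.linspace(centers.min() - 0.5, centers.max() + 0.5, 400)
    h = span[1] - span[0]
    curv = np.max(np.abs(np.gradient(pot.grad(span), h)))
    k_total = k_w + curv
    if dt * k_total / friction >= 0.1:
        raise ValueError(
            f"unstable integration: dt*k_total/friction = "
            f"{dt * k_total / friction:.3f} >= 0.1; reduce dt"
        )
    rng = np.random.default_rng(seed)
    xi = centers.copy()
    sigma = np.sqrt(2.0 * kBT * dt / friction)
    n_total = n_equilibration + n_samples
    out = np.empty((n_total, centers.size))
    for s in range(n_total):
        for _ in range(thin):
            force = -(pot.grad(xi) + k_w * (xi - centers))
            xi = xi + force * dt / friction + sigma * rng.standard_normal(centers.size)
        out[s] = xi
    span_width = centers.max() - centers.min() + 1.0
    if np.any(np.abs(out - centers) > 10.0 * span_width):
        raise ValueError("divergent trajectory: reduce dt or increase friction")
    return [
        UmbrellaWindow(
            center=float(c),
            k_w=float(k_w),
            samples=out[n_equilibration:, i],
            n_equilibration=n_equilibration,
        )
        for i, c in enumerate(centers)
    ]


def _histograms(windows, edges):
    counts = np.stack(
        [np.histogram(w.samples, bins=edges)[0].astype(float) for w in windows]
    )
    return counts


def wham(
    windows,
    n_bins: int = 200,
    grid: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    tc: ThermoConstants = ThermoConstants(),
    f_init: np.ndarray | None = None,
    check_overlap: bool = True,
) -> PMFProfile:
    """Self-consistent WHAM over harmonically biased windows.

    Iterates the unbiased density rho(xi) and per-window free energies f_i
    until max |delta f_i| < ``tol`` (kcal/mol); G = -kBT ln rho, shifted to
    min 0. Unvisited bins carry NaN. Raises :class:`WindowOverlapError` when
    adjacent windows share no occupied bins and :class:`ConvergenceError`
    (carrying the residual) when the iteration cap is hit.
    """
    windows = sorted(windows, key=lambda w: w.center)
    kBT = tc.kBT_kcal_mol
    if grid is None:
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        grid = np.asarray(grid, dtype=float)
        edges = grid
        n_bins = edges.size - 1
    centers_bin = 0.5 * (edges[:-1] + edges[1:])
    counts = _histograms(windows, edges)  # (n_windows, n_bins)
    if check_overlap:
        occupied = counts > 0
        for i in range(len(windows) - 1):
            if not np.any(occupied[i] & occupied[i + 1]):
                raise WindowOverlapError(
                    f"windows at {windows[i].center:.3g} and "
                    f"{windows[i + 1].center:.3g} share no occupied bins"
                )
    N = counts.sum(axis=1)  # samples per window
    num = counts.sum(axis=0)  # total counts per bin
    bias = np.stack(
        [0.5 * w.k_w * (centers_bin - w.center) ** 2 for w in windows]
    )  # (n_windows, n_bins)
    boltz = np.exp(-bias / kBT)
    f = np.zeros(len(windows)) if f_init is None else np.asarray(f_init, float).copy()

    residual = np.inf
    residual_trace: list[float] = []
    for it in range(int(max_iter)):
        denom = (N * np.exp(f / kBT)) @ boltz  # (n_bins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = np.where(denom > 0, num / denom, 0.0)
        z = boltz @ rho  # (n_windows,)
        f_new = -kBT * np.log(np.maximum(z, 1e-300))
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        residual_trace.append(residual)
        f = f_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {residual:.3g} kcal/mol)",
            last_iterate=f,
        )
    with np.errstate(divide="ignore"):
        G = np.where(rho > 0, -kBT * np.log(np.maximum(rho, 1e-300)), np.nan)
    G = G - np.nanmin(G)
    return PMFProfile(
        xi=centers_bin,
        G=G,
        meta={
            "n_iterations": it + 1,
            "residual_kcal_mol": residual,
            "residual_trace": residual_trace,
            "window_free_energies": f.tolist(),
            "edges": edges,
        },
    )


def _block_length(samples: np.ndarray) -> int:
    """Integrated-autocorrelation block length (initial positive sequence)."""
    x = samples - samples.mean()
    n = x.size
    if n < 8 or x.std() == 0:
        return 1
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * x.var())
    tau = 1.0
    for k in range(1, min(n // 2, 500)):
        if acf[k] <= 0:
            break
        tau += 2.0 * acf[k]
    return max(1, int(np.ceil(tau)))


def bootstrap_pmf(
    windows,
    B: int = 200,
    seed: int = 0,
    n_bins: int = 200,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    tc: ThermoConstants = ThermoConstants(),
    check_overlap: bool = True,
) -> PMFProfile:
    """Baseline WHAM profile with per-bin block-bootstrap SD.

    Each of the ``B`` resamples rebuilds every window from contiguous blocks
    (block length = the window's integrated autocorrelation time) and re-runs
    WHAM warm-started from the baseline window free energies; the per-bin SD
    is taken across min-zeroed resampled profiles.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    baseline = wham(
        windows,
        n_bins=n_bins,
        tol=tol,
        max_iter=max_iter,
        tc=tc,
        check_overlap=check_overlap,
    )
    edges = baseline.meta["edges"]
    f0 = np.asarray(baseline.meta["window_free_energies"])
    rng = np.random.default_rng(seed)
    blocks = [_block_length(w.samples) for w in windows]
    profiles = np.empty((B, baseline.G.size))
    order = np.argsort([w.center for w in windows])
    windows = [windows[i] for i in order]
    for b in range(B):
        resampled = []
        for w, blk in zip(windows, blocks):
            n = w.samples.size
            n_blocks = int(np.ceil(n / blk))
            starts = rng.integers(0, max(1, n - blk + 1), size=n_blocks)
            idx = (starts[:, None] + np.arange(blk)[None, :]).ravel()[:n]
            resampled.append(
                UmbrellaWindow(center=w.center, k_w=w.k_w, samples=w.samples[idx])
            )
        prof = wham(
            resampled,
            grid=edges,
            tol=tol,
            max_iter=max_iter,
            tc=tc,
            f_init=f0,
            check_overlap=False,
        )
        profiles[b] = prof.G
    import warnings

    with warnings.catch_warnings():
        # bins never visited are all-NaN columns; their SD stays NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(profiles, axis=0, ddof=1)
        boot_mean = np.nanmean(profiles, axis=0)
    return PMFProfile(
        xi=baseline.xi,
        G=baseline.G,
        sd=sd,
        meta={
            **baseline.meta,
            "bootstrap_B": B,
            "block_lengths": blocks,
            "bootstrap_mean": boot_mean,
        },
    )


def deltaG_and_barrier(
    pmf: PMFProfile,
    plateau_fraction: float = 0.1,
    min_prominence: float = 0.25,
) -> tuple[float, float]:
    """(deltaG_bu, barrier height) in kcal/mol from a PMF profile.

    The unbound plateau is the mean over the last ``plateau_fraction`` of the
    coordinate range; the bound well is the profile minimum before that
    region; the barrier is the maximum between the two (it equals the well
    depth when the profile rises monotonically to the plateau). Profiles with
    no minimum at least ``min_prominence`` kcal/mol below the plateau (flat
    or monotonically decreasing profiles) raise :class:`NoBoundStateError`.
    """
    G, xi = pmf.G, pmf.xi
    n = G.size
    n_plateau = max(2, int(np.ceil(plateau_fraction * n)))
    plateau_region = G[n - n_plateau :]
    if np.all(np.isnan(plateau_region)):
        raise NoBoundStateError("plateau region has no sampled bins")
    plateau = float(np.nanmean(plateau_region))
    body = G[: n - n_plateau]
    if np.all(np.isnan(body)):
        raise NoBoundStateError("profile body has no sampled bins")
    i_well = int(np.nanargmin(body))
    g_well = float(body[i_well])
    between = G[i_well : n - n_plateau + 1]
    g_max = float(np.nanmax(between))
    deltaG = g_well - plateau
    barrier = g_max - g_well
    if deltaG > -min_prominence:
        raise NoBoundStateError(
            f"no bound well: minimum is only {-deltaG:.3g} kcal/mol below "
            f"the plateau (need >= {min_prominence})"
        )
    return deltaG, barrier
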