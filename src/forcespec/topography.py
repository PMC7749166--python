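"""AFM height-map analysis: bilayer referencing, particle detection,
protrusion-height / FWHM-diameter measurement, population mixture fitting,
receptor-orientation calls and multiplex adhesion-event overlay.

Membrane receptors reconstituted in a bilayer protrude differently depending
on which face points up; the protrusion height above the bilayer therefore
calls the orientation (below the threshold: extracellular face up).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max
from sklearn.mixture import GaussianMixture

from .exceptions import ConvergenceError, ReferencingError

__all__ = [
    "HeightMap",
    "Particle",
    "ModeFit",
    "ORIENTATION_THRESHOLD_NM",
    "flatten_and_reference",
    "detect_particles",
    "measure_particle",
    "measure_particles",
    "fit_modes",
    "em_log_likelihood_trace",
    "classify_orientation",
    "overlay_events",
    "read_height_map",
    "write_height_map",
]

#: Protrusion-height threshold (nm) separating the two orientation classes.
ORIENTATION_THRESHOLD_NM = 1.75
_FWHM_PER_SIGMA = 2.354820045385861  # 2 sqrt(2 ln 2)


@dataclass
class HeightMap:
    """Raster of heights (nm) with its lateral calibration (nm/px)."""

    grid: np.ndarray
    pixel_size: float = 1.0
    channel: str = "height"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("height map must be 2-D")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("height map contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0 nm/px")


@dataclass
class Particle:
    """One detected membrane-protruding particle."""

    centroid: tuple[float, float]  # (row, col), sub-pixel
    protrusion_height: float  # nm above the local bilayer
    fwhm_diameter: float  # nm
    orientation: str = "unassigned"


@dataclass
class ModeFit:
    """Gaussian-mixture fit of a 1-D population, components sorted by mean."""

    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    n_iter: int


def flatten_and_reference(
    hm: HeightMap, bin_width: float = 0.05, min_background_fraction: float = 0.5
) -> HeightMap:
    """Remove the sample tilt and set the bilayer level to zero.

    A least-squares plane is fitted and removed; the bilayer level is the
    mode of the height histogram (``bin_width`` nm bins) and is subtracted; a
    second plane fit restricted to near-bilayer pixels removes the residual
    tilt bias that protruding particles introduce. Raises
    :class:`ReferencingError` when no dominant background level exists.
    """
    grid = hm.grid
    rows, cols = grid.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    A = np.column_stack([rr.ravel(), cc.ravel(), np.ones(grid.size)])

    def plane_fit(mask=None):
        if mask is None:
            coef, *_ = np.linalg.lstsq(A, grid.ravel(), rcond=None)
        else:
            coef, *_ = np.linalg.lstsq(A[mask.ravel()], grid.ravel()[mask.ravel()], rcond=None)
        return (coef[0] * rr + coef[1] * cc + coef[2])

    flat = grid - plane_fit()

    def histogram_mode(values):
        lo, hi = values.min(), values.max()
        nbins = max(3, int(np.ceil((hi - lo) / bin_width)))
        counts, edges = np.histogram(values, bins=nbins)
        j = int(np.argmax(counts))
        return 0.5 * (edges[j] + edges[j + 1]), counts[j] / values.size

    mode, _ = histogram_mode(flat.ravel())
    near = np.abs(flat - mode) < 6 * bin_width
    if near.mean() < min_background_fraction:
        raise ReferencingError(
            f"only {near.mean():.0%} of pixels near the modal level "
            f"(need >= {min_background_fraction:.0%}); no dominant bilayer"
        )
    flat = grid - plane_fit(mask=near)
    mode, _ = histogram_mode(flat.ravel())
    return HeightMap(grid=flat - mode, pixel_size=hm.pixel_size, channel=hm.channel)


def detect_particles(
    hm: HeightMap, min_height: float = 0.5, min_separation: float = 6.0
) -> list[tuple[int, int]]:
    """Particle seeds: local maxima with prominence above ``min_height`` nm
    and no duplicates within ``min_separation`` nm. The map must be
    referenced (bilayer at 0)."""
    min_dist_px = max(1, int(round(min_separation / hm.pixel_size)))
    peaks = peak_local_max(
        hm.grid,
        min_distance=min_dist_px,
        threshold_abs=min_height,
        exclude_border=False,
    )
    return [tuple(p) for p in peaks]


def _log_paraboloid_apex(patch: np.ndarray) -> tuple[float, float, float] | None:
    """Sub-pixel apex of a 3x3 patch assuming a Gaussian shape (the log of a
    Gaussian is an exact paraboloid). Returns (drow, dcol, amplitude) or None
    if the patch is not strictly positive / not peaked."""
    if np.any(patch <= 0):
        return None
    L = np.log(patch)
    dr = 0.5 * (L[2, 1] - L[0, 1])
    dc = 0.5 * (L[1, 2] - L[1, 0])
    drr = L[2, 1] - 2 * L[1, 1] + L[0, 1]
    dcc = L[1, 2] - 2 * L[1, 1] + L[1, 0]
    if drr >= 0 or dcc >= 0:
        return None
    r_off = np.clip(-dr / drr, -1, 1)
    c_off = np.clip(-dc / dcc, -1, 1)
    # separable paraboloid maximum: L0 - dr^2/(2 drr) - dc^2/(2 dcc)
    log_amp = L[1, 1] + 0.5 * (dr * r_off + dc * c_off)
    return float(r_off), float(c_off), float(np.exp(log_amp))


def measure_particle(
    hm: HeightMap,
    seed: tuple[int, int],
    mode: str = "radial",
) -> Particle | None:
    """Protrusion height and FWHM diameter of one detected particle.

    Height is the sub-pixel apex (Gaussian/log-paraboloid interpolation on
    the 3x3 neighbourhood) minus the local bilayer level (median of the
    analysis-window border). The diameter is the full width at half the
    protrusion height on the radially averaged profile about the apex
    (``mode="section"`` uses a single row cross-section instead, for parity
    with line-profile practice). Particles whose analysis window would cross
    the map edge are skipped with a warning (returns None).
    """
    grid, px = hm.grid, hm.pixel_size
    r0, c0 = int(seed[0]), int(seed[1])
    rows, cols = grid.shape
    h_apex0 = grid[r0, c0]
    if h_apex0 <= 0:
        return None
    # rough half-height radius along +col to size the analysis window
    r_half = 1
    for d in range(1, min(cols - 1 - c0, 200)):
        if grid[r0, c0 + d] < 0.5 * h_apex0:
            r_half = d
            break
    else:
        r_half = min(cols - 1 - c0, 5)
    W = int(np.clip(3 * r_half, 5, 10 * r_half))
    if r0 - W < 0 or r0 + W >= rows or c0 - W < 0 or c0 + W >= cols:
        warnings.warn(
            f"particle at {seed} touches the map edge; measurement skipped",
            stacklevel=2,
        )
        return None
    window = grid[r0 - W : r0 + W + 1, c0 - W : c0 + W + 1]
    border = np.concatenate(
        [window[0:2].ravel(), window[-2:].ravel(), window[:, 0:2].ravel(), window[:, -2:].ravel()]
    )
    background = float(np.median(border))

    patch = grid[r0 - 1 : r0 + 2, c0 - 1 : c0 + 2] - background
    apex = _log_paraboloid_apex(patch)
    if apex is None:
        # fall back to a plain paraboloid through the 3x3 heights
        L = patch
        dr = 0.5 * (L[2, 1] - L[0, 1])
        dc = 0.5 * (L[1, 2] - L[1, 0])
        drr = L[2, 1] - 2 * L[1, 1] + L[0, 1]
        dcc = L[1, 2] - 2 * L[1, 1] + L[1, 0]
        r_off = float(np.clip(-dr / drr, -1, 1)) if drr < 0 else 0.0
        c_off = float(np.clip(-dc / dcc, -1, 1)) if dcc < 0 else 0.0
        amp = float(L[1, 1] + 0.5 * (dr * r_off + dc * c_off))
        apex = (r_off, c_off, amp)
    r_off, c_off, height = apex
    rc, cc_ = r0 + r_off, c0 + c_off

    rr, cc = np.mgrid[r0 - W : r0 + W + 1, c0 - W : c0 + W + 1]
    if mode == "radial":
        radii = np.hypot(rr - rc, cc - cc_) * px
        values = window - background
        bin_w = 0.5 * px
        nb = int(W * px / bin_w)
        idx = np.minimum((radii / bin_w).astype(int), nb)
        sums = np.bincount(idx.ravel(), weights=values.ravel(), minlength=nb + 1)
        cnts = np.bincount(idx.ravel(), minlength=nb + 1)
        occupied = cnts > 0  # thin annuli near the apex can be empty
        prof = sums[occupied] / cnts[occupied]
        r_centers = ((np.arange(nb + 1) + 0.5) * bin_w)[occupied]
    elif mode == "section":
        line = grid[r0, c0 - W : c0 + W + 1] - background
        d = np.abs(np.arange(-W, W + 1) - c_off) * px
        order = np.argsort(d)
        r_centers, prof = d[order], line[order]
    else:
        raise ValueError(f"unknown measurement mode {mode!r}")

    half = 0.5 * height
    below = np.nonzero(prof < half)[0]
    below = below[below > 0]
    if below.size == 0:
        return None
    j = below[0]
    x0, x1 = r_centers[j - 1], r_centers[j]
    y0, y1 = prof[j - 1], prof[j]
    r_half_nm = x0 + (y0 - half) / max(y0 - y1, 1e-12) * (x1 - x0)
    fwhm = 2.0 * r_half_nm
    return Particle(
        centroid=(float(rc), float(cc_)),
        protrusion_height=float(height),
        fwhm_diameter=float(fwhm),
    )


def measure_particles(
    hm: HeightMap, seeds, mode: str = "radial", threshold: float = ORIENTATION_THRESHOLD_NM
) -> pd.DataFrame:
    """Measure and orientation-classify all seeds into a particle table."""
    rows = []
    for i, seed in enumerate(seeds):
        p = measure_particle(hm, seed, mode=mode)
        if p is None:
            continue
        p.orientation = classify_orientation(p.protrusion_height, threshold)
        rows.append(
            {
                "id": i,
                "row": p.centroid[0],
                "col": p.centroid[1],
                "height_nm": p.protrusion_height,
                "fwhm_nm": p.fwhm_diameter,
                "orientation": p.orientation,
            }
        )
    return pd.DataFrame(
        rows, columns=["id", "row", "col", "height_nm", "fwhm_nm", "orientation"]
    )


def fit_modes(values, k: int, seed: int = 0, tol: float = 1e-8) -> ModeFit:
    """Maximum-likelihood Gaussian mixture of a 1-D sample by EM.

    k-means initialization, fixed seed for determinism, components sorted by
    mean. Requires n >= 10 k. Raises :class:`ConvergenceError` if EM does not
    converge within the iteration cap.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.shape[0] < 10 * k:
        raise ValueError(f"need at least {10 * k} values for k={k}, got {x.shape[0]}")
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        tol=tol,
        reg_covar=1e-10,
        max_iter=1000,
        n_init=5,
        init_params="kmeans",
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(x)
    if not gm.converged_:
        raise ConvergenceError(
            f"EM did not converge in {gm.n_iter_} iterations "
            f"(last lower bound {gm.lower_bound_:.6g})"
        )
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    return ModeFit(
        k=k,
        means=means[order],
        sds=sds[order],
        weights=weights[order],
        log_likelihood=float(gm.score(x) * x.shape[0]),
        n_iter=int(gm.n_iter_),
    )


def em_log_likelihood_trace(values, k: int, seed: int = 0, max_iter: int = 200):
    """Per-iteration EM mean log-likelihood path (for monotonicity checks)."""
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        tol=0.0,
        reg_covar=1e-10,
        max_iter=1,
        n_init=1,
        init_params="kmeans",
        random_state=seed,
        warm_start=True,
    )
    trace = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(max_iter):
            gm.fit(x)
            trace.append(float(gm.lower_bound_))
            if len(trace) > 2 and abs(trace[-1] - trace[-2]) < 1e-12:
                break
    return np.asarray(trace)


def classify_orientation(height: float, threshold: float = ORIENTATION_THRESHOLD_NM) -> str:
    """Orientation call from the protrusion height: below the threshold the
    extracellular face points up; at or above it the intracellular face does
    (boundary assigned to the upper class by convention)."""
    return "extracellular_up" if height < threshold else "intracellular_up"


def overlay_events(
    particles: pd.DataFrame,
    events_by_probe: dict,
    pixel_size: float = 1.0,
    probe_for_orientation: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Overlay per-probe specific adhesion events on the particle table.

    Each event pixel is assigned to the nearest particle within that
    particle's FWHM (as a radius, in nm); events with no particle in range
    are tallied unassigned. Returns a per-event assignment table and a
    summary with the orientation/probe concordance fraction: the fraction of
    assigned events whose probe chemistry matches the particle's
    height-based orientation call.
    """
    if probe_for_orientation is None:
        probe_for_orientation = {
            "extracellular_up": "ligand",
            "intracellular_up": "his_tag",
        }
    rows = []
    n_unassigned = 0
    coords = particles[["row", "col"]].to_numpy(dtype=float) if len(particles) else np.empty((0, 2))
    for probe, pixels in events_by_probe.items():
        for (er, ec) in pixels:
            if coords.shape[0] == 0:
                n_unassigned += 1
                continue
            d = np.hypot(coords[:, 0] - er, coords[:, 1] - ec) * pixel_size
            j = int(np.argmin(d))
            radius = float(particles.iloc[j]["fwhm_nm"])
            if d[j] > radius:
                n_unassigned += 1
                continue
            orient = str(particles.iloc[j]["orientation"])
            rows.append(
                {
                    "particle_id": particles.iloc[j]["id"],
                    "event_row": er,
                    "event_col": ec,
                    "probe": probe,
                    "orientation": orient,
                    "concordant": probe_for_orientation.get(orient) == probe,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["particle_id", "event_row", "event_col", "probe", "orientation", "concordant"],
    )
    n_assigned = len(table)
    concordance = float(table["concordant"].mean()) if n_assigned else float("nan")
    summary = {
        "n_assigned": n_assigned,
        "n_unassigned": n_unassigned,
        "concordance": concordance,
    }
    return table, summary


def read_height_map(path, pixel_size: float | None = None) -> HeightMap:
    """Read a CSV numeric matrix or single-channel TIFF; pixel size from the
    ``.meta.json`` sidecar unless given."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        grid = np.asarray(tifffile.imread(path), dtype=float)
    else:
        grid = np.loadtxt(path, delimiter=",")
    if pixel_size is None:
        sidecar = path.with_suffix(".meta.json")
        pixel_size = 1.0
        if sidecar.exists():
            pixel_size = float(json.loads(sidecar.read_text()).get("pixel_size_nm", 1.0))
    return HeightMap(grid=grid, pixel_size=pixel_size)


def write_height_map(hm: HeightMap, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, hm.grid.astype(np.float32))
    else:
        np.savetxt(path, hm.grid, delimiter=",", fmt="%.6g")
    path.with_suffix(".meta.json").write_text(
        json.dumps({"pixel_size_nm": hm.pixel_size, "channel": hm.channel})
    )
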