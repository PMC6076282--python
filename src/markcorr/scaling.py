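"""Plot-size accuracy/precision experiment.

Rasterize the marked pattern at a ladder of grid-cell sizes; in each cell the
*measured* value is the sum of the marks of the trees it contains and the
*expected* value is the tree count times the grand mean mark (the value an
area-based assessment would predict from density alone).  Regressing measured
on expected per hectare gives a slope (accuracy: 1 = unbiased) and an R^2
(precision) per cell size.  Distance- and density-dependent marks depress the
slope at fine resolutions; both recover toward 1 as cells grow and local
structure averages out.

Cell sizes may be given in meters (square cells) or arc-seconds, converted at
a reference latitude: the east-west width carries a cos(latitude) factor, so
arc-second cells are slightly rectangular.  At latitude 12 deg S a 3.33
arc-second cell is close to one hectare.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm

from .geometry import MarkedPattern

__all__ = [
    "ScalingConfig",
    "ScalingResult",
    "arcsec_to_m",
    "rasterize",
    "scaling_regression",
    "scaling_curve",
    "residual_correlogram",
]

EARTH_RADIUS_M = 6371008.8

#: the arc-second ladder used for the published experiment
DEFAULT_ARCSEC_SIZES = (1.0, 2.5, 3.33, 5.0, 7.5, 10.0, 15.0, 20.0, 30.0, 40.0)


def arcsec_to_m(size_arcsec: float, ref_latitude_deg: float) -> tuple[float, float]:
    """(east-west width, north-south height) in meters of an arc-second cell."""
    rad_per_arcsec = math.pi / 648000.0
    ns = size_arcsec * rad_per_arcsec * EARTH_RADIUS_M
    ew = ns * math.cos(math.radians(ref_latitude_deg))
    return ew, ns


@dataclass(frozen=True)
class ScalingConfig:
    cell_sizes: tuple[float, ...] = DEFAULT_ARCSEC_SIZES
    units: str = "arcsec"  # or "m"
    ref_latitude_deg: float = -12.0
    min_coverage: float = 1.0  # fraction of cell inside the window required
    regression_mode: str = "through_origin"  # or "with_intercept"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.cell_sizes):
            raise ValueError("cell sizes must be positive")
        if not (0 < self.min_coverage <= 1):
            raise ValueError("min_coverage must be in (0, 1]")
        if self.units not in ("arcsec", "m"):
            raise ValueError(f"unknown units {self.units!r}")
        if self.regression_mode not in ("through_origin", "with_intercept"):
            raise ValueError(f"unknown regression_mode {self.regression_mode!r}")

    def cell_dims_m(self, size: float) -> tuple[float, float]:
        if self.units == "m":
            return float(size), float(size)
        return arcsec_to_m(size, self.ref_latitude_deg)


def rasterize(
    pattern: MarkedPattern,
    mark: str = "seed",
    cell_size: float | tuple[float, float] = 100.0,
    min_coverage: float = 1.0,
) -> pd.DataFrame:
    """Per-cell tree counts, measured and expected mark totals.

    The grid of each concession is aligned to its window bounding box
    (origin at the min corner); cell membership is half-open,
    [x0, x0+w) x [y0, y0+h).  Cells with less than ``min_coverage`` of
    their area inside the window are dropped.  ``expected`` is count times
    the grand mean of the mark over all trees pooled across concessions.
    ``cell_size`` is meters, scalar (square) or (width, height).
    """
    w, h = (cell_size, cell_size) if np.isscalar(cell_size) else cell_size
    col = {"seed": "seed_kg", "agb": "agb_kg"}[mark]
    values = pattern.trees[col].to_numpy(dtype=float)
    grand_mean = float(np.nanmean(values))
    cell_area_ha = w * h / 1e4

    rows = []
    for cid, win in pattern.windows.items():
        x0, y0, x1, y1 = win.boundary.bounds
        if w > (x1 - x0) or h > (y1 - y0):
            warnings.warn(
                f"cell size {w:.0f}x{h:.0f} m exceeds window {cid!r} extent; "
                "degenerate single-cell grid",
                stacklevel=2,
            )
        nx = max(1, math.ceil((x1 - x0) / w))
        ny = max(1, math.ceil((y1 - y0) / h))
        sel = (pattern.trees["concession_id"] == cid).to_numpy()
        xy = pattern.coords(sel)
        v = values[sel]
        ix = np.minimum(((xy[:, 0] - x0) / w).astype(int), nx - 1)
        iy = np.minimum(((xy[:, 1] - y0) / h).astype(int), ny - 1)
        flat = ix * ny + iy
        count = np.bincount(flat, minlength=nx * ny)
        defined = ~np.isnan(v)
        measured = np.bincount(flat[defined], weights=v[defined], minlength=nx * ny)

        gx, gy = np.divmod(np.arange(nx * ny), ny)
        cx = x0 + (gx + 0.5) * w
        cy = y0 + (gy + 0.5) * h
        cells = shapely.box(x0 + gx * w, y0 + gy * h, x0 + (gx + 1) * w, y0 + (gy + 1) * h)
        cov = shapely.area(shapely.intersection(cells, win.boundary)) / (w * h)
        keep = cov >= min(min_coverage, 1.0 - 1e-9)
        tab = pd.DataFrame(
            {
                "concession_id": cid,
                "cx": cx,
                "cy": cy,
                "count": count,
                "measured": measured,
                "expected": count * grand_mean,
            }
        )[keep]
        rows.append(tab)
    out = pd.concat(rows, ignore_index=True)
    out["cell_area_ha"] = cell_area_ha
    out["measured_ha"] = out["measured"] / cell_area_ha
    out["expected_ha"] = out["expected"] / cell_area_ha
    return out


def scaling_regression(cells: pd.DataFrame, mode: str = "through_origin") -> dict:
    """OLS of measured per-ha on expected per-ha.

    Through-origin mode keeps empty cells (structurally 0 = 0); intercept
    mode drops them so zero-inflation does not dominate the fit.  Returns
    slope, its 95% CI, and R^2 (uncentered for through-origin fits).
    """
    tab = cells if mode == "through_origin" else cells[cells["count"] > 0]
    if len(tab) < 3:
        raise ValueError("need at least 3 cells for the scaling regression")
    x = tab["expected_ha"].to_numpy()
    y = tab["measured_ha"].to_numpy()
    if np.var(x) == 0 and mode == "with_intercept":
        raise ValueError("zero variance in expected values; regression undefined")
    X = x[:, None] if mode == "through_origin" else sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    slope = fit.params[-1]
    lo, hi = fit.conf_int(alpha=0.05)[-1]
    return {
        "slope": float(slope),
        "slope_lo": float(lo),
        "slope_hi": float(hi),
        "r2": float(fit.rsquared),
        "n_cells": int(len(tab)),
    }


@dataclass
class ScalingResult:
    mark: str
    config: ScalingConfig
    table: pd.DataFrame  # one row per cell size: cell_area_ha, slope, CI, r2
    cell_tables: dict[float, pd.DataFrame] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"Plot-size scaling of {self.mark} ({self.config.regression_mode})"]
        lines.append(
            self.table[["cell_size", "cell_area_ha", "slope", "slope_lo", "slope_hi", "r2", "n_cells"]]
            .to_string(index=False, float_format=lambda v: f"{v:.4g}")
        )
        return "\n".join(lines)


def scaling_curve(
    pattern: MarkedPattern, mark: str = "seed", config: ScalingConfig = ScalingConfig()
) -> ScalingResult:
    """Slope and R^2 of expected-vs-measured regressions along the cell-size
    ladder, ordered by cell area."""
    if len(config.cell_sizes) < 2:
        raise ValueError("need at least 2 cell sizes")
    rows = []
    cell_tables = {}
    for size in config.cell_sizes:
        dims = config.cell_dims_m(size)
        cells = rasterize(pattern, mark, dims, config.min_coverage)
        reg = scaling_regression(cells, config.regression_mode)
        rows.append({"cell_size": size, "cell_area_ha": dims[0] * dims[1] / 1e4, **reg})
        cell_tables[size] = cells
    table = pd.DataFrame(rows).sort_values("cell_area_ha", ignore_index=True)
    return ScalingResult(mark, config, table, cell_tables)


def residual_correlogram(
    centroids: np.ndarray,
    residuals: np.ndarray,
    bin_edges: Sequence[float],
    n_shuffle: int = 99,
    seed: int = 0,
) -> pd.DataFrame:
    """Distance-binned Moran-type correlation of regression residuals.

    For every pair of cells whose centroid distance falls in a bin, the
    statistic is mean(z_i * z_j) / var(z) with z the centred residuals --
    near 0 everywhere for spatially independent residuals.  A pointwise
    permutation envelope (``n_shuffle`` shuffles of the residuals over the
    cell locations, rank-1 min/max bounds) flags bins outside it.
    """
    centroids = np.asarray(centroids, dtype=float)
    z = np.asarray(residuals, dtype=float)
    z = z - z.mean()
    var = z.var()
    edges = np.asarray(bin_edges, dtype=float)
    nb = edges.size - 1
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    iu, ju = np.triu_indices(len(z), k=1)
    dist = d[iu, ju]
    bin_idx = np.digitize(dist, edges) - 1
    ok = (bin_idx >= 0) & (bin_idx < nb)
    if not ok.any():
        raise ValueError("no cell pairs fall in the requested distance bins")
    iu, ju, bin_idx = iu[ok], ju[ok], bin_idx[ok]
    n_pairs = np.bincount(bin_idx, minlength=nb)

    def stat(zz: np.ndarray) -> np.ndarray:
        s = np.bincount(bin_idx, weights=zz[iu] * zz[ju], minlength=nb)
        with np.errstate(invalid="ignore"):
            return s / np.where(n_pairs > 0, n_pairs, np.nan) / var

    obs = stat(z)
    rng = np.random.default_rng(seed)
    sims = np.array([stat(rng.permutation(z)) for _ in range(n_shuffle)])
    lo = np.nanmin(sims, axis=0)
    hi = np.nanmax(sims, axis=0)
    mid = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore"):
        significant = (obs < lo) | (obs > hi)
    return pd.DataFrame(
        {
            "r": mid,
            "correlation": obs,
            "n_pairs": n_pairs,
            "envelope_lo": lo,
            "envelope_hi": hi,
            "significant": significant & ~np.isnan(obs),
        }
    )
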