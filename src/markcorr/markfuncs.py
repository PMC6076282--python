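"""The four mark correlation functions with binning schemes and edge rules.

All four statistics relate a quantitative mark (seed production or AGB,
normalized per concession) to the spatial configuration of conspecific trees:

f1  mean normalized mark of trees whose nearest conspecific neighbour lies in
    a distance band [r-h, r+h] -- values below/above 1 indicate trees with
    close/far neighbours perform worse/better than the concession average;
f2  Pearson correlation between the marks of nearest-neighbour pairs whose
    separation lies in [r-h, r+h] (a mark analogue of Moran's I, after
    Schlather);
f3  "density correlation": Pearson correlation between a focal tree's mark
    and its number of conspecific neighbours within radius r (cumulative);
f4  "aggregation correlation": Pearson correlation between a focal tree's
    mark and the Clark-Evans aggregation index of its neighbourhood,
    2*dbar*sqrt(rho), where dbar is the mean nearest-neighbour distance among
    neighbourhood members and rho the concession density (index 1 under
    complete spatial randomness, <1 for aggregated, >1 for regular spacing).

Edge corrections: f1/f2 drop trees closer to the concession boundary than to
their nearest neighbour; f3/f4 restrict focal trees to those at least r from
the boundary; within f4 neighbourhoods, members closer to the circumference
than to their nearest fellow member are excluded from dbar.

Each ``fN_*`` function returns a :class:`MarkFunctionResult`.  The paired
``fN_plan`` builders return a callable that recomputes the statistic for a
new mark vector on *fixed* geometry -- this is what makes the 199-replicate
mark-shuffling null model cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import MarkedPattern, nearest_neighbours, neighbour_counts

__all__ = [
    "BinSpec",
    "make_bins",
    "SCHEMES",
    "edge_filter_nn",
    "MarkFunctionResult",
    "NeighbourhoodAggregation",
    "clark_evans_neighbourhood",
    "aggregation_indices",
    "f1_nn_mark_mean",
    "f2_schlather",
    "f3_density_corr",
    "f4_aggregation_corr",
    "f1_plan",
    "f2_plan",
    "f3_plan",
    "f4_plan",
]

NEAR_MAX_M = 150.0
FAR_MAX_M = 350.0


@dataclass(frozen=True)
class BinSpec:
    """Distance-bin centers ``r`` with common half-width ``h``.

    A distance d belongs to bin k iff r_k - h <= d <= r_k + h; a distance on
    a boundary shared by two bins is assigned to the lower bin (deterministic
    tie-break).  For the cumulative regime the centers are the radii
    themselves and ``halfwidth`` is 0.
    """

    centers: np.ndarray
    halfwidth: float
    regime: str  # "near" | "far" | "cumulative"

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", c)
        if np.any(np.diff(c) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if self.regime != "cumulative" and self.halfwidth <= 0:
            raise ValueError("halfwidth must be positive")

    @property
    def n_bins(self) -> int:
        return self.centers.size

    def assign(self, dists: np.ndarray) -> np.ndarray:
        """Bin index for each distance, -1 where no bin matches."""
        d = np.asarray(dists, dtype=float)
        out = np.full(d.shape, -1, dtype=int)
        h = self.halfwidth
        for k, r in enumerate(self.centers):  # ascending: first match = lowest bin
            sel = (out == -1) & (d >= r - h) & (d <= r + h)
            out[sel] = k
        return out


def _near_scheme(h: float) -> BinSpec:
    # contiguous bins of width 2h starting at 0: centers h, 3h, ... while
    # the upper edge stays within the near range
    centers = np.arange(h, NEAR_MAX_M - h + 1e-9, 2 * h)
    return BinSpec(centers, h, "near")


def _far_scheme(h: float) -> BinSpec:
    centers = np.arange(NEAR_MAX_M + h, FAR_MAX_M - h + 1e-9, 2 * h)
    return BinSpec(centers, h, "far")


SCHEMES: dict[str, Callable[[], BinSpec]] = {
    "near_1.5": lambda: _near_scheme(1.5),
    "near_5": lambda: _near_scheme(5.0),
    "near_10": lambda: _near_scheme(10.0),
    "far_3": lambda: _far_scheme(3.0),
    "far_10": lambda: _far_scheme(10.0),
    "far_20": lambda: _far_scheme(20.0),
    "cumulative": lambda: BinSpec(np.arange(10.0, FAR_MAX_M + 1e-9, 10.0), 0.0, "cumulative"),
}


def make_bins(scheme: str) -> BinSpec:
    """Named binning scheme: ``near_{1.5,5,10}``, ``far_{3,10,20}`` or
    ``cumulative`` (radii 10, 20, ..., 350 m)."""
    try:
        return SCHEMES[scheme]()
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}") from None


def edge_filter_nn(
    pattern: MarkedPattern, neighbours: pd.DataFrame | None = None
) -> tuple[np.ndarray, float]:
    """Boolean retention mask for the nearest-neighbour edge rule.

    A tree is retained iff its distance to the concession boundary is at
    least its nearest-neighbour distance (trees without a neighbour are
    dropped).  Returns ``(mask, dropped_fraction)``.
    """
    nbr = pattern.neighbours() if neighbours is None else neighbours
    nn = nbr["nn_dist"].to_numpy()
    edge = nbr["edge_dist"].to_numpy()
    mask = ~np.isnan(nn) & (edge >= nn)
    return mask, 1.0 - mask.mean() if len(mask) else 0.0


@dataclass
class MarkFunctionResult:
    """Per-bin observed statistic with (optional) envelope bounds."""

    function: str  # f1_nn_mean | f2_schlather | f3_density | f4_aggregation
    mark: str
    scheme: str
    table: pd.DataFrame  # r, statistic, n_contributing, envelope_lo, envelope_hi, significant, flag
    dropped_fraction: float = np.nan

    def significant_bins(self) -> pd.DataFrame:
        return self.table[self.table["significant"].fillna(False)]


def _result_table(r, stat, n, flags) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "r": r,
            "statistic": stat,
            "n_contributing": n,
            "envelope_lo": np.nan,
            "envelope_hi": np.nan,
            "significant": pd.array([pd.NA] * len(r), dtype="boolean"),
            "flag": flags,
        }
    )


def _grouped_pearson(bin_idx: np.ndarray, x: np.ndarray, y: np.ndarray, n_bins: int):
    """Pearson correlation of (x, y) within each bin, via per-bin sums.

    Returns (corr, n) arrays of length n_bins; corr is NaN for bins with
    fewer than 2 pairs or zero variance in either variable.
    """
    ok = bin_idx >= 0
    b, x, y = bin_idx[ok], x[ok], y[ok]
    n = np.bincount(b, minlength=n_bins).astype(float)
    sx = np.bincount(b, weights=x, minlength=n_bins)
    sy = np.bincount(b, weights=y, minlength=n_bins)
    sxx = np.bincount(b, weights=x * x, minlength=n_bins)
    syy = np.bincount(b, weights=y * y, minlength=n_bins)
    sxy = np.bincount(b, weights=x * y, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / np.where(n > 0, n, np.nan)
        vx = sxx - sx**2 / np.where(n > 0, n, np.nan)
        vy = syy - sy**2 / np.where(n > 0, n, np.nan)
        corr = cov / np.sqrt(vx * vy)
    corr[(n < 2) | ~np.isfinite(corr)] = np.nan
    return corr, n.astype(int)


# -- f1: nearest-neighbour mark mean -----------------------------------------


def f1_plan(pattern: MarkedPattern, bins: BinSpec):
    """Statistic closure for f1 on fixed geometry.

    Returns ``(stat_fn, r, n_contributing, dropped_fraction)`` where
    ``stat_fn(marks)`` gives the per-bin mean normalized mark.
    """
    nbr = pattern.neighbours()
    mask, dropped = edge_filter_nn(pattern, nbr)
    idx = np.flatnonzero(mask)
    bin_idx = bins.assign(nbr["nn_dist"].to_numpy()[idx])
    ok = bin_idx >= 0
    idx, bin_idx = idx[ok], bin_idx[ok]
    n = np.bincount(bin_idx, minlength=bins.n_bins)

    def stat_fn(marks: np.ndarray) -> np.ndarray:
        s = np.bincount(bin_idx, weights=marks[idx], minlength=bins.n_bins)
        with np.errstate(invalid="ignore"):
            return s / np.where(n > 0, n, np.nan)

    return stat_fn, bins.centers, n, dropped


def f1_nn_mark_mean(
    pattern: MarkedPattern, marks: np.ndarray, bins: BinSpec, mark_name: str = "seed"
) -> MarkFunctionResult:
    """Mean normalized mark of trees by nearest-neighbour distance band."""
    stat_fn, r, n, dropped = f1_plan(pattern, bins)
    if (n == 0).all():
        raise ValueError("all distance bins are empty")
    stat = stat_fn(np.asarray(marks, dtype=float))
    flags = np.where(n == 0, "empty", "")
    res = MarkFunctionResult("f1_nn_mean", mark_name, bins.regime, _result_table(r, stat, n, flags))
    res.dropped_fraction = dropped
    return res


# -- f2: Schlather pair correlation ------------------------------------------


def f2_plan(pattern: MarkedPattern, bins: BinSpec, unique_pairs: bool = False):
    """Statistic closure for f2: Pearson correlation over (focal, nearest
    neighbour) mark pairs per distance band.

    By default pairs are ordered per focal tree, so mutual nearest
    neighbours contribute twice (per-tree symmetric weighting);
    ``unique_pairs=True`` switches to each unordered pair once.
    """
    nbr = pattern.neighbours()
    mask, dropped = edge_filter_nn(pattern, nbr)
    i = np.flatnonzero(mask)
    j = nbr["nn_index"].to_numpy()[i]
    if unique_pairs:
        a, b = np.minimum(i, j), np.maximum(i, j)
        _, keep = np.unique(np.stack([a, b]), axis=1, return_index=True)
        i, j = i[np.sort(keep)], j[np.sort(keep)]
    bin_idx = bins.assign(nbr["nn_dist"].to_numpy()[i])
    n = np.bincount(bin_idx[bin_idx >= 0], minlength=bins.n_bins)

    def stat_fn(marks: np.ndarray) -> np.ndarray:
        corr, _ = _grouped_pearson(bin_idx, marks[i], marks[j], bins.n_bins)
        return corr

    return stat_fn, bins.centers, n, dropped


def f2_schlather(
    pattern: MarkedPattern,
    marks: np.ndarray,
    bins: BinSpec,
    mark_name: str = "seed",
    unique_pairs: bool = False,
) -> MarkFunctionResult:
    """Pearson correlation between the marks of nearest-neighbour pairs."""
    stat_fn, r, n, dropped = f2_plan(pattern, bins, unique_pairs)
    stat = stat_fn(np.asarray(marks, dtype=float))
    flags = np.where(n == 0, "empty", np.where(n < 3, "unstable", ""))
    flags = np.where((n >= 2) & np.isnan(stat), "zero_variance", flags)
    res = MarkFunctionResult("f2_schlather", mark_name, bins.regime, _result_table(r, stat, n, flags))
    res.dropped_fraction = dropped
    return res


# -- f3: density correlation ---------------------------------------------------


def f3_plan(pattern: MarkedPattern, radii: Sequence[float]):
    """Statistic closure for f3: per cumulative radius r, the Pearson
    correlation between focal marks and neighbour counts within r, over
    focal trees at least r from the boundary."""
    radii = np.asarray(radii, dtype=float)
    counts = neighbour_counts(pattern, radii)
    edge = pattern.neighbours()["edge_dist"].to_numpy()
    focal_sets = [np.flatnonzero(edge >= r) for r in radii]
    n = np.array([len(f) for f in focal_sets])

    def stat_fn(marks: np.ndarray) -> np.ndarray:
        out = np.full(radii.size, np.nan)
        for k, f in enumerate(focal_sets):
            if len(f) < 2:
                continue
            x, y = marks[f], counts[f, k].astype(float)
            vx, vy = x.var(), y.var()
            if vx > 0 and vy > 0:
                out[k] = np.corrcoef(x, y)[0, 1]
        return out

    return stat_fn, radii, n, counts


def f3_density_corr(
    pattern: MarkedPattern,
    marks: np.ndarray,
    radii: Sequence[float] | None = None,
    mark_name: str = "seed",
) -> MarkFunctionResult:
    """Correlation between a tree's mark and its conspecific crowding 0..r."""
    if radii is None:
        radii = make_bins("cumulative").centers
    stat_fn, r, n, _ = f3_plan(pattern, radii)
    stat = stat_fn(np.asarray(marks, dtype=float))
    flags = np.where(n < 3, "too_few_focals", "")
    flags = np.where((n >= 3) & np.isnan(stat), "zero_variance", flags)
    return MarkFunctionResult("f3_density", mark_name, "cumulative", _result_table(r, stat, n, flags))


# -- Clark-Evans neighbourhood aggregation ------------------------------------


@dataclass
class NeighbourhoodAggregation:
    """Clark-Evans aggregation summary of one circular neighbourhood."""

    focal_id: str
    radius: float
    n_members: int
    n_used: int  # members surviving the circumference edge rule
    mean_nn_dist: float  # dbar (m), NaN if undefined
    expected_nn_dist: float  # 1 / (2 sqrt(rho)) (m)
    ce_index: float  # 2 dbar sqrt(rho); NaN if undefined

    @property
    def defined(self) -> bool:
        return not np.isnan(self.ce_index)


def _neighbourhood_ce(xy_members: np.ndarray, dist_to_focal: np.ndarray, r: float, rho: float):
    """(dbar, n_members, n_used, ce) for one neighbourhood.

    Members' nearest-neighbour distances are computed among the members
    themselves; members closer to the circumference of the disc than to
    their nearest fellow member are excluded from dbar (their true nearest
    neighbour may lie outside the disc).
    """
    m = len(xy_members)
    if m < 2:
        return np.nan, m, 0, np.nan
    if m <= 32:
        diff = xy_members[:, None, :] - xy_members[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
    else:
        nn = cKDTree(xy_members).query(xy_members, k=2)[0][:, 1]
    keep = (r - dist_to_focal) >= nn
    n_used = int(keep.sum())
    if n_used < 2:
        return np.nan, m, n_used, np.nan
    dbar = float(nn[keep].mean())
    return dbar, m, n_used, 2.0 * dbar * np.sqrt(rho)


def clark_evans_neighbourhood(
    pattern: MarkedPattern, focal_id: str, r: float
) -> NeighbourhoodAggregation:
    """Aggregation index of the conspecific neighbourhood of one focal tree.

    The index is dbar / E(d) = 2 dbar sqrt(rho) with rho the focal tree's
    concession density in trees per m^2: 1 for complete spatial randomness,
    <1 for aggregated and >1 for regularly spaced neighbourhoods.  Requires
    the focal tree to be at least r from the concession boundary.
    """
    trees = pattern.trees
    pos = np.flatnonzero((trees["tree_id"] == str(focal_id)).to_numpy())
    if len(pos) == 0:
        raise KeyError(f"unknown tree_id {focal_id!r}")
    i = int(pos[0])
    cid = trees["concession_id"].iat[i]
    edge = pattern.neighbours()["edge_dist"].to_numpy()[i]
    if edge < r:
        raise ValueError(
            f"focal tree {focal_id!r} is {edge:.1f} m from the boundary, "
            f"closer than the neighbourhood radius {r} m"
        )
    xy = pattern.coords()
    members_mask = (trees["concession_id"] == cid).to_numpy()
    members_mask[i] = False
    d_focal = np.linalg.norm(xy - xy[i], axis=1)
    members = np.flatnonzero(members_mask & (d_focal <= r))
    rho = pattern.windows[cid].density_rho
    dbar, m, n_used, ce = _neighbourhood_ce(xy[members], d_focal[members], r, rho)
    return NeighbourhoodAggregation(
        focal_id=str(focal_id),
        radius=r,
        n_members=m,
        n_used=n_used,
        mean_nn_dist=dbar,
        expected_nn_dist=1.0 / (2.0 * np.sqrt(rho)),
        ce_index=ce,
    )


def aggregation_indices(
    pattern: MarkedPattern, r: float, focal: np.ndarray | None = None
) -> np.ndarray:
    """Clark-Evans index of every (or selected) focal tree's neighbourhood.

    Returns an array aligned to the tree table, NaN where the index is
    undefined (fewer than two usable members) or the tree is not in
    ``focal``.  No boundary eligibility is enforced here; callers apply it.
    """
    xy = pattern.coords()
    out = np.full(pattern.n_trees, np.nan)
    want = np.zeros(pattern.n_trees, dtype=bool)
    want[np.arange(pattern.n_trees) if focal is None else focal] = True
    from .geometry import _concession_groups

    for cid, members in _concession_groups(pattern):
        sel = members[want[members]]
        if len(sel) == 0 or len(members) < 3:
            continue
        rho = pattern.windows[cid].density_rho
        tree = cKDTree(xy[members])
        neigh_lists = tree.query_ball_point(xy[sel], r)
        for f, neigh in zip(sel, neigh_lists):
            nb = members[neigh]
            nb = nb[nb != f]
            d_focal = np.linalg.norm(xy[nb] - xy[f], axis=1)
            *_, ce = _neighbourhood_ce(xy[nb], d_focal, r, rho)
            out[f] = ce
    return out


# -- f4: aggregation correlation ----------------------------------------------


def f4_plan(pattern: MarkedPattern, radii: Sequence[float]):
    """Statistic closure for f4: per radius r, Pearson correlation between
    focal marks and the neighbourhood Clark-Evans index, over eligible
    focal trees (boundary distance >= r) with a defined index."""
    radii = np.asarray(radii, dtype=float)
    edge = pattern.neighbours()["edge_dist"].to_numpy()
    focal_sets = []
    ce_sets = []
    for r in radii:
        eligible = np.flatnonzero(edge >= r)
        ce = aggregation_indices(pattern, r, eligible)
        defined = eligible[~np.isnan(ce[eligible])]
        focal_sets.append(defined)
        ce_sets.append(ce[defined])
    n = np.array([len(f) for f in focal_sets])

    def stat_fn(marks: np.ndarray) -> np.ndarray:
        out = np.full(radii.size, np.nan)
        for k, (f, ce) in enumerate(zip(focal_sets, ce_sets)):
            if len(f) < 2:
                continue
            x = marks[f]
            if x.var() > 0 and ce.var() > 0:
                out[k] = np.corrcoef(x, ce)[0, 1]
        return out

    return stat_fn, radii, n, ce_sets


def f4_aggregation_corr(
    pattern: MarkedPattern,
    marks: np.ndarray,
    radii: Sequence[float] | None = None,
    mark_name: str = "seed",
) -> MarkFunctionResult:
    """Correlation between a tree's mark and neighbourhood aggregation.

    Positive values mean trees in more aggregated neighbourhoods (index < 1)
    carry lower marks; negative values the opposite.
    """
    if radii is None:
        radii = make_bins("cumulative").centers
    stat_fn, r, n, _ = f4_plan(pattern, radii)
    stat = stat_fn(np.asarray(marks, dtype=float))
    flags = np.where(n < 3, "too_few_focals", "")
    flags = np.where((n >= 3) & np.isnan(stat), "zero_variance", flags)
    return MarkFunctionResult(
        "f4_aggregation", mark_name, "cumulative", _result_table(r, stat, n, flags)
    )
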