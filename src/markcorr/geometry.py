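"""Marked-pattern data model and spatial primitives.

A *marked point pattern* here is a set of trees with planar metric
coordinates, each carrying quantitative marks (annual seed production in kg
and above-ground biomass in kg) and belonging to exactly one polygonal
management unit ("concession").  All spatial statistics in this package are
computed per concession: nearest-neighbour searches, neighbour counts and
edge corrections never cross a concession boundary, and marks are normalized
by the mean of the concession a tree belongs to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

__all__ = [
    "MarkedTree",
    "ConcessionWindow",
    "MarkedPattern",
    "nearest_neighbours",
    "neighbour_counts",
    "boundary_distances",
    "normalize_marks",
    "geographic_to_projected",
]

#: tolerance (m) for deciding whether a tree lies inside its window
INSIDE_TOL = 1e-6

#: minimum diameter at breast height (cm) admitted to the inventory
DBH_MIN_CM = 10.0


@dataclass(frozen=True)
class MarkedTree:
    """One tree: location, concession membership, DBH and marks.

    ``dbh_cm`` may be ``None`` for trees whose diameter was not measured;
    such trees carry seed marks only and are excluded from biomass analyses.
    """

    tree_id: str
    x: float
    y: float
    concession_id: str
    dbh_cm: float | None = None
    seed_kg: float = 0.0
    agb_kg: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"tree {self.tree_id!r}: non-finite coordinates")
        if self.dbh_cm is not None and not (self.dbh_cm >= DBH_MIN_CM):
            raise ValueError(
                f"tree {self.tree_id!r}: dbh {self.dbh_cm} cm below the "
                f"inventory threshold of {DBH_MIN_CM} cm"
            )
        if self.seed_kg < 0:
            raise ValueError(f"tree {self.tree_id!r}: negative seed mark")
        if self.agb_kg is not None and self.agb_kg <= 0:
            raise ValueError(f"tree {self.tree_id!r}: non-positive AGB mark")


@dataclass
class ConcessionWindow:
    """Concession polygon plus the derived quantities used for normalization.

    ``density_rho`` is in trees per square meter (the unit in which the
    Clark–Evans expectation 1/(2*sqrt(rho)) yields meters).
    """

    concession_id: str
    boundary: Polygon
    n_trees: int = 0
    area_ha: float = field(init=False, default=0.0)
    density_rho: float = field(init=False, default=0.0)
    mean_seed_kg: float = math.nan
    mean_agb_kg: float = math.nan

    def __post_init__(self) -> None:
        if not self.boundary.is_valid or self.boundary.is_empty:
            raise ValueError(f"window {self.concession_id!r}: invalid polygon")
        area_m2 = self.boundary.area
        if area_m2 <= 0:
            raise ValueError(f"window {self.concession_id!r}: zero area")
        self.area_ha = area_m2 / 1e4
        self.density_rho = self.n_trees / area_m2


_TREE_COLUMNS = ["tree_id", "concession_id", "x", "y", "dbh_cm", "seed_kg", "agb_kg"]


class MarkedPattern:
    """Trees plus their concession windows, validated.

    Parameters
    ----------
    trees:
        DataFrame with columns ``tree_id, concession_id, x, y, dbh_cm,
        seed_kg, agb_kg`` (``dbh_cm``/``agb_kg`` may be NaN) or an iterable
        of :class:`MarkedTree`.
    windows:
        Mapping from concession id to a shapely ``Polygon`` in the same
        planar metric coordinates (meters) as the trees.
    crs:
        Either ``"projected"`` (meters; required for all statistics) or
        ``"geographic"``, which is refused -- project first, e.g. with
        :func:`geographic_to_projected`.
    """

    def __init__(
        self,
        trees: pd.DataFrame | Iterable[MarkedTree],
        windows: Mapping[str, Polygon],
        crs: str = "projected",
    ) -> None:
        if crs != "projected":
            raise ValueError(
                "MarkedPattern requires planar metric coordinates; got crs="
                f"{crs!r}. Project lon/lat first (geographic_to_projected)."
            )
        if isinstance(trees, pd.DataFrame):
            df = trees.copy()
        else:
            df = pd.DataFrame(
                [
                    (t.tree_id, t.concession_id, t.x, t.y, t.dbh_cm, t.seed_kg, t.agb_kg)
                    for t in trees
                ],
                columns=_TREE_COLUMNS,
            )
        missing = set(_TREE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"tree table missing columns: {sorted(missing)}")
        df = df[_TREE_COLUMNS].reset_index(drop=True)
        df["tree_id"] = df["tree_id"].astype(str)
        df["concession_id"] = df["concession_id"].astype(str)
        for c in ("x", "y", "dbh_cm", "seed_kg", "agb_kg"):
            df[c] = pd.to_numeric(df[c], errors="raise").astype(float)

        if df["tree_id"].duplicated().any():
            dup = df.loc[df["tree_id"].duplicated(), "tree_id"].iloc[0]
            raise ValueError(f"duplicate tree_id {dup!r}")
        if not np.isfinite(df[["x", "y"]].to_numpy()).all():
            raise ValueError("non-finite coordinates in tree table")
        bad_dbh = df["dbh_cm"].notna() & (df["dbh_cm"] < DBH_MIN_CM)
        if bad_dbh.any():
            ids = df.loc[bad_dbh, "tree_id"].tolist()[:5]
            raise ValueError(
                f"dbh below the {DBH_MIN_CM} cm inventory threshold for trees {ids}"
            )
        if (df["seed_kg"] < 0).any():
            raise ValueError("negative seed marks")

        unresolved = set(df["concession_id"]) - set(map(str, windows))
        if unresolved:
            raise ValueError(f"trees reference unknown concessions: {sorted(unresolved)}")

        self.trees = df
        self._polygons = {str(k): v for k, v in windows.items()}
        self._validate_containment()
        self._windows = self._build_windows()
        self._nbr_cache: pd.DataFrame | None = None

    # -- construction helpers -------------------------------------------------

    def _validate_containment(self) -> None:
        pts = shapely.points(self.trees["x"].to_numpy(), self.trees["y"].to_numpy())
        for cid, poly in self._polygons.items():
            mask = (self.trees["concession_id"] == cid).to_numpy()
            if not mask.any():
                continue
            ok = shapely.dwithin(pts[mask], poly, INSIDE_TOL)
            if not ok.all():
                bad = self.trees.loc[mask, "tree_id"].to_numpy()[~ok][:5]
                raise ValueError(
                    f"trees outside window {cid!r}: {list(bad)} "
                    f"(tolerance {INSIDE_TOL} m)"
                )

    def _build_windows(self) -> dict[str, ConcessionWindow]:
        out: dict[str, ConcessionWindow] = {}
        counts = self.trees["concession_id"].value_counts()
        seed_means = self.trees.groupby("concession_id")["seed_kg"].mean()
        agb_means = self.trees.groupby("concession_id")["agb_kg"].mean()
        for cid, poly in self._polygons.items():
            w = ConcessionWindow(cid, poly, n_trees=int(counts.get(cid, 0)))
            w.mean_seed_kg = float(seed_means.get(cid, math.nan))
            w.mean_agb_kg = float(agb_means.get(cid, math.nan))
            out[cid] = w
        return out

    # -- public surface -------------------------------------------------------

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def windows(self) -> dict[str, ConcessionWindow]:
        return self._windows

    def window_table(self) -> pd.DataFrame:
        """Per-concession summary: area, tree count, density, mark means."""
        rows = [
            {
                "concession_id": w.concession_id,
                "area_ha": w.area_ha,
                "n_trees": w.n_trees,
                "density_per_ha": w.density_rho * 1e4,
                "mean_seed_kg": w.mean_seed_kg,
                "mean_agb_kg": w.mean_agb_kg,
            }
            for w in self._windows.values()
        ]
        return pd.DataFrame(rows)

    def density_per_tree(self) -> np.ndarray:
        """Concession density rho (trees per m^2) aligned to the tree table."""
        rho = {cid: w.density_rho for cid, w in self._windows.items()}
        return self.trees["concession_id"].map(rho).to_numpy(dtype=float)

    def coords(self, mask: np.ndarray | None = None) -> np.ndarray:
        xy = self.trees[["x", "y"]].to_numpy(dtype=float)
        return xy if mask is None else xy[mask]

    def neighbours(self) -> pd.DataFrame:
        """Cached :func:`nearest_neighbours` result for this pattern."""
        if self._nbr_cache is None:
            self._nbr_cache = nearest_neighbours(self)
        return self._nbr_cache


# -- spatial primitives -------------------------------------------------------


def _concession_groups(pattern: MarkedPattern):
    """Yield (concession_id, positional index array) per concession."""
    idx = pattern.trees.groupby("concession_id", sort=True).indices
    for cid in sorted(idx):
        yield cid, np.asarray(idx[cid])


def nearest_neighbours(pattern: MarkedPattern) -> pd.DataFrame:
    """Strictly nearest conspecific neighbour of every tree, per concession.

    Returns a DataFrame aligned to ``pattern.trees`` with columns ``nn_index``
    (positional index of the neighbour, -1 if the concession has a single
    tree), ``nn_id``, ``nn_dist`` (m, NaN if undefined) and ``edge_dist``
    (m, distance to the window boundary).  Ties in distance are broken by the
    smallest neighbour ``tree_id``; coincident trees in one concession are an
    error.
    """
    n = pattern.n_trees
    nn_index = np.full(n, -1, dtype=int)
    nn_dist = np.full(n, np.nan)
    xy = pattern.coords()
    ids = pattern.trees["tree_id"].to_numpy()

    for cid, members in _concession_groups(pattern):
        m = len(members)
        if m < 2:
            continue
        tree = cKDTree(xy[members])
        k = min(m, 8)
        dist, idx = tree.query(xy[members], k=k)
        d1 = dist[:, 1]
        if np.any(d1 == 0.0):
            i = int(np.argmax(d1 == 0.0))
            a, b = ids[members[i]], ids[members[idx[i, 1]]]
            raise ValueError(
                f"duplicate coordinates in concession {cid!r}: trees {a!r} and {b!r}"
            )
        # deterministic tie-break: among all neighbours at the minimal
        # distance, pick the smallest tree_id
        for i in range(m):
            tied = np.flatnonzero(dist[i, 1:] == d1[i]) + 1
            cand = members[idx[i, tied]]
            if len(tied) == k - 1 and k < m:
                # ties may extend beyond k: fall back to a full scan
                dd = np.linalg.norm(xy[members] - xy[members[i]], axis=1)
                dd[i] = np.inf
                cand = members[dd == d1[i]]
            best = cand[np.argmin(ids[cand])] if len(cand) > 1 else cand[0]
            nn_index[members[i]] = best
            nn_dist[members[i]] = d1[i]

    nn_id = np.where(nn_index >= 0, ids[nn_index], None)
    return pd.DataFrame(
        {
            "tree_id": ids,
            "nn_index": nn_index,
            "nn_id": nn_id,
            "nn_dist": nn_dist,
            "edge_dist": boundary_distances(pattern),
        }
    )


def neighbour_counts(
    pattern: MarkedPattern, radii: Sequence[float]
) -> np.ndarray:
    """Number of conspecific neighbours within 0..r, per tree and radius.

    Counts exclude the focal tree and never cross concession boundaries.
    Returns an integer array of shape ``(n_trees, len(radii))``; counts are
    monotone non-decreasing along the radius axis.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        raise ValueError("radii list is empty")
    if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing and positive")
    xy = pattern.coords()
    counts = np.zeros((pattern.n_trees, radii.size), dtype=int)
    for _, members in _concession_groups(pattern):
        if len(members) < 2:
            continue
        tree = cKDTree(xy[members])
        for j, r in enumerate(radii):
            c = tree.query_ball_point(xy[members], r, return_length=True)
            counts[members, j] = c - 1  # exclude the focal tree
    return counts


def boundary_distances(pattern: MarkedPattern) -> np.ndarray:
    """Euclidean distance from every tree to its window boundary (m)."""
    xy = pattern.coords()
    out = np.full(pattern.n_trees, np.nan)
    pts = shapely.points(xy[:, 0], xy[:, 1])
    for cid, members in _concession_groups(pattern):
        ring = pattern.windows[cid].boundary.exterior
        out[members] = shapely.distance(pts[members], ring)
    return out


def normalize_marks(pattern: MarkedPattern, mark: str = "seed") -> np.ndarray:
    """Marks divided by the mean of all trees in the same concession.

    ``mark`` is ``"seed"`` or ``"agb"``.  For AGB, trees without a DBH (NaN
    AGB) are excluded from the concession mean and their normalized mark is
    NaN.  Within each concession the mean of the (defined) normalized marks
    is exactly 1, which removes between-concession mean differences.
    """
    col = {"seed": "seed_kg", "agb": "agb_kg"}[mark]
    values = pattern.trees[col].to_numpy(dtype=float)
    means = pattern.trees.groupby("concession_id")[col].transform("mean").to_numpy()
    defined = ~np.isnan(values)
    if np.any(defined & ~(means > 0)):
        bad = pattern.trees.loc[defined & ~(means > 0), "concession_id"].unique()
        raise ValueError(
            f"cannot normalize {mark!r} marks: non-positive concession mean in {list(bad)}"
        )
    return values / means


# -- geographic helper --------------------------------------------------------

_WGS84_A = 6378137.0
_WGS84_F = 1 / 298.257223563


def geographic_to_projected(
    lon: np.ndarray | float,
    lat: np.ndarray | float,
    zone: int = 19,
    south: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Project WGS84 lon/lat (degrees) to UTM easting/northing (m).

    Standard Transverse Mercator series (sub-meter accuracy within a UTM
    zone); default zone 19S covers Madre de Dios, Peru.  Use this before
    building a :class:`MarkedPattern` from geographic inputs.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    a, f = _WGS84_A, _WGS84_F
    e2 = f * (2 - f)
    ep2 = e2 / (1 - e2)
    k0 = 0.9996
    lon0 = math.radians(zone * 6 - 183)
    phi = np.radians(lat)
    dlam = np.radians(lon) - lon0

    N = a / np.sqrt(1 - e2 * np.sin(phi) ** 2)
    T = np.tan(phi) ** 2
    C = ep2 * np.cos(phi) ** 2
    A = np.cos(phi) * dlam
    # meridional arc length (Snyder 1987, eq. 3-21)
    M = a * (
        (1 - e2 / 4 - 3 * e2**2 / 64 - 5 * e2**3 / 256) * phi
        - (3 * e2 / 8 + 3 * e2**2 / 32 + 45 * e2**3 / 1024) * np.sin(2 * phi)
        + (15 * e2**2 / 256 + 45 * e2**3 / 1024) * np.sin(4 * phi)
        - (35 * e2**3 / 3072) * np.sin(6 * phi)
    )
    easting = 500000.0 + k0 * N * (
        A + (1 - T + C) * A**3 / 6 + (5 - 18 * T + T**2 + 72 * C - 58 * ep2) * A**5 / 120
    )
    northing = k0 * (
        M
        + N
        * np.tan(phi)
        * (
            A**2 / 2
            + (5 - T + 9 * C + 4 * C**2) * A**4 / 24
            + (61 - 58 * T + T**2 + 600 * C - 330 * ep2) * A**6 / 720
        )
    )
    if south:
        northing = northing + 10000000.0
    return easting, northing
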