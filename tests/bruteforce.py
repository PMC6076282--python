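"""Independent brute-force reference implementations.

Pure O(n^2) loops over explicit pairwise distances, no spatial index and no
shared code paths with the package; used as oracles for exact-equivalence
tests on small patterns.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as _st


def pairwise_dists(xy: np.ndarray) -> np.ndarray:
    n = len(xy)
    d = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = math.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1])
    return d


def nn_brute(xy: np.ndarray, ids: np.ndarray, cids: np.ndarray):
    """(nn_index, nn_dist) per tree; same-concession only; ties -> smallest id."""
    n = len(xy)
    d = pairwise_dists(xy)
    nn_index = np.full(n, -1)
    nn_dist = np.full(n, np.nan)
    for i in range(n):
        cand = [j for j in range(n) if j != i and cids[j] == cids[i]]
        if not cand:
            continue
        dmin = min(d[i, j] for j in cand)
        tied = [j for j in cand if d[i, j] == dmin]
        nn_index[i] = min(tied, key=lambda j: ids[j])
        nn_dist[i] = dmin
    return nn_index, nn_dist


def counts_brute(xy: np.ndarray, cids: np.ndarray, radii) -> np.ndarray:
    n = len(xy)
    d = pairwise_dists(xy)
    out = np.zeros((n, len(radii)), dtype=int)
    for i in range(n):
        for k, r in enumerate(radii):
            out[i, k] = sum(
                1 for j in range(n) if j != i and cids[j] == cids[i] and d[i, j] <= r
            )
    return out


def bin_of(dist: float, centers, h: float) -> int:
    for k, r in enumerate(centers):
        if r - h <= dist <= r + h:
            return k
    return -1


def pearson_brute(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / math.sqrt(sxx * syy)


def f1_brute(nn_dist, edge_dist, marks, centers, h):
    """Per-bin mean mark of retained trees (edge_dist >= nn_dist)."""
    out = np.full(len(centers), np.nan)
    cnt = np.zeros(len(centers), dtype=int)
    sums = np.zeros(len(centers))
    for i in range(len(marks)):
        if np.isnan(nn_dist[i]) or edge_dist[i] < nn_dist[i]:
            continue
        k = bin_of(nn_dist[i], centers, h)
        if k >= 0:
            sums[k] += marks[i]
            cnt[k] += 1
    out[cnt > 0] = sums[cnt > 0] / cnt[cnt > 0]
    return out, cnt


def f2_brute(nn_index, nn_dist, edge_dist, marks, centers, h):
    """Per-bin Pearson over ordered (focal, nearest-neighbour) mark pairs."""
    pairs = [[] for _ in centers]
    for i in range(len(marks)):
        if np.isnan(nn_dist[i]) or edge_dist[i] < nn_dist[i]:
            continue
        k = bin_of(nn_dist[i], centers, h)
        if k >= 0:
            pairs[k].append((marks[i], marks[nn_index[i]]))
    out = np.full(len(centers), np.nan)
    for k, pk in enumerate(pairs):
        if len(pk) >= 2:
            out[k] = pearson_brute([a for a, _ in pk], [b for _, b in pk])
    return out


def f3_brute(xy, cids, edge_dist, marks, radii):
    counts = counts_brute(xy, cids, radii)
    out = np.full(len(radii), np.nan)
    for k, r in enumerate(radii):
        sel = [i for i in range(len(marks)) if edge_dist[i] >= r]
        if len(sel) >= 2:
            out[k] = pearson_brute([marks[i] for i in sel], [float(counts[i, k]) for i in sel])
    return out


def ce_brute(xy, cids, rho_by_cid, focal: int, r: float) -> float:
    """Clark-Evans index of one neighbourhood, straight from the definitions."""
    d = pairwise_dists(xy)
    members = [
        j
        for j in range(len(xy))
        if j != focal and cids[j] == cids[focal] and d[focal, j] <= r
    ]
    if len(members) < 2:
        return float("nan")
    kept_nn = []
    for j in members:
        nnj = min(d[j, k] for k in members if k != j)
        if (r - d[focal, j]) >= nnj:
            kept_nn.append(nnj)
    if len(kept_nn) < 2:
        return float("nan")
    dbar = sum(kept_nn) / len(kept_nn)
    return 2.0 * dbar * math.sqrt(rho_by_cid[cids[focal]])


def f4_brute(xy, cids, rho_by_cid, edge_dist, marks, radii):
    out = np.full(len(radii), np.nan)
    for k, r in enumerate(radii):
        xs, ys = [], []
        for i in range(len(marks)):
            if edge_dist[i] < r:
                continue
            ce = ce_brute(xy, cids, rho_by_cid, i, r)
            if not math.isnan(ce):
                xs.append(marks[i])
                ys.append(ce)
        if len(xs) >= 2:
            out[k] = pearson_brute(xs, ys)
    return out


def rasterize_brute(xy, marks, origin, w, h, nx, ny):
    """(count, measured) grids by explicit point-in-cell tests."""
    count = np.zeros((nx, ny), dtype=int)
    measured = np.zeros((nx, ny))
    for i in range(len(xy)):
        for ix in range(nx):
            for iy in range(ny):
                x0 = origin[0] + ix * w
                y0 = origin[1] + iy * h
                inx = (x0 <= xy[i, 0] < x0 + w) or (ix == nx - 1 and xy[i, 0] == x0 + w)
                iny = (y0 <= xy[i, 1] < y0 + h) or (iy == ny - 1 and xy[i, 1] == y0 + h)
                if inx and iny:
                    count[ix, iy] += 1
                    measured[ix, iy] += marks[i]
    return count, measured


def ols_brute(x, y, through_origin: bool):
    """Closed-form OLS with 95% slope CI."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if through_origin:
        slope = float(np.sum(x * y) / np.sum(x * x))
        resid = y - slope * x
        dof = n - 1
        se = math.sqrt(float(np.sum(resid**2)) / dof / float(np.sum(x * x)))
        r2 = 1.0 - float(np.sum(resid**2)) / float(np.sum(y**2))  # uncentered
    else:
        mx, my = x.mean(), y.mean()
        sxx = float(np.sum((x - mx) ** 2))
        slope = float(np.sum((x - mx) * (y - my)) / sxx)
        intercept = my - slope * mx
        resid = y - intercept - slope * x
        dof = n - 2
        se = math.sqrt(float(np.sum(resid**2)) / dof / sxx)
        r2 = 1.0 - float(np.sum(resid**2)) / float(np.sum((y - my) ** 2))
    t = _st.t.ppf(0.975, dof)
    return slope, (slope - t * se, slope + t * se), r2
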