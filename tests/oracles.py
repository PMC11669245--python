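"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where feasible, the libraries)
they are checking: hulls by exhaustive facet search, Otsu by direct
histogram scan, Mann-Whitney by full enumeration of group assignments.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def hull_2d_brute(points: np.ndarray) -> tuple[float, float]:
    """(area, perimeter) of the convex hull by exhaustive edge search.

    An ordered pair (i, j) is a hull edge iff every other point lies
    left-of-or-on the line i -> j.  Works for clouds in general position and
    for grids (collinear points on an edge are tolerated).
    """
    pts = np.asarray(points, float)
    n = len(pts)
    edges = []
    for i in range(n):
        d = pts - pts[i]
        for j in range(n):
            if i == j:
                continue
            cross = d[:, 0] * d[j, 1] - d[:, 1] * d[j, 0]
            if np.all(cross >= -1e-12):
                edges.append((i, j, float(np.hypot(*d[j]))))
    # order edges into a closed polygon starting from the lexicographic min
    nxt = {}
    for i, j, L in edges:
        # among collinear candidates keep the farthest continuation
        if i not in nxt or L > nxt[i][1]:
            nxt[i] = (j, L)
    start = min(nxt)
    poly = [start]
    cur = nxt[start][0]
    while cur != start:
        poly.append(cur)
        cur = nxt[cur][0]
    P = pts[poly]
    x, y = P[:, 0], P[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    perim = float(np.sqrt(((P - np.roll(P, -1, axis=0)) ** 2).sum(axis=1)).sum())
    return float(area), perim


def hull_3d_brute(points: np.ndarray) -> tuple[float, float]:
    """(volume, surface area) by exhaustive facet-plane search.

    Every triple whose plane has all points on one side defines a supporting
    plane; planes are deduplicated (handling coplanar clouds such as lattice
    corners), each facet polygon is measured with the 2D brute hull in-plane,
    and the volume is assembled from centroid pyramids.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    c = pts.mean(axis=0)
    scale = max(1.0, float(np.abs(pts).max()))
    planes: dict[tuple, tuple[np.ndarray, float]] = {}
    for i, j, k in combinations(range(n), 3):
        a, b, d = pts[i], pts[j], pts[k]
        nrm = np.cross(b - a, d - a)
        mag = np.linalg.norm(nrm)
        if mag < 1e-12 * scale**2:
            continue
        nrm = nrm / mag
        s = (pts - a) @ nrm
        tol = 1e-9 * scale
        if np.all(s <= tol):
            pass
        elif np.all(s >= -tol):
            nrm = -nrm
            s = -s
        else:
            continue
        off = float(nrm @ a)
        key = (round(nrm[0], 7), round(nrm[1], 7), round(nrm[2], 7), round(off, 6))
        if key not in planes:
            planes[key] = (nrm, off)
    volume = 0.0
    area = 0.0
    for nrm, off in planes.values():
        on = pts[np.abs(pts @ nrm - off) <= 1e-8 * scale]
        # orthonormal in-plane basis
        u = np.cross(nrm, [1.0, 0.0, 0.0])
        if np.linalg.norm(u) < 1e-6:
            u = np.cross(nrm, [0.0, 1.0, 0.0])
        u /= np.linalg.norm(u)
        v = np.cross(nrm, u)
        uv = np.stack([on @ u, on @ v], axis=1)
        if len(uv) < 3:
            continue
        a2, _ = hull_2d_brute(uv)
        area += a2
        volume += a2 * abs(off - nrm @ c) / 3.0
    return float(volume), float(area)


def otsu_brute(field: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold by direct scan of all histogram splits.

    Returns the bin-centre threshold maximizing between-class variance, the
    same convention as the scanned 256-bin histogram method.
    """
    counts, edges = np.histogram(np.asarray(field).ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    best, best_t = -1.0, centers[0]
    total = counts.sum()
    for t in range(1, nbins):
        w0 = counts[:t].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:t] * centers[:t]).sum() / w0
        mu1 = (counts[t:] * centers[t:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best:
            best, best_t = var, centers[t - 1]
    return float(best_t)


def mannwhitney_exact_brute(a, b) -> tuple[float, float]:
    """(U of sample a, exact two-sided p) by full enumeration.

    Assumes no ties.  Two-sided p counts assignments at least as extreme as
    the observed U on either side of the symmetric null distribution.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    ranks = pooled.argsort().argsort() + 1  # no ties by assumption
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    lo = min(u_obs, n * m - u_obs)
    count = 0
    total = 0
    idx = range(n + m)
    rank_all = np.sort(ranks)
    for comb in combinations(idx, n):
        r = rank_all[list(comb)].sum()
        u = r - n * (n + 1) / 2
        if min(u, n * m - u) <= lo + 1e-9:
            count += 1
        total += 1
    return float(u_obs), count / total
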