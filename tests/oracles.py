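"""Independent brute-force oracles used to validate the implementation paths.

These deliberately re-derive results with the most literal possible
algorithms (quadratic scans, exhaustive enumeration) and stay independent
of the package internals they check.
"""

from itertools import combinations
from math import comb

import numpy as np

NOISE = -1


def brute_dbscan(points, eps: float, min_pts: int) -> np.ndarray:
    """Quadratic-time DBSCAN with the documented deterministic semantics."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        return np.empty(0, dtype=int)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    sp = pts[order]
    dist = np.linalg.norm(sp[:, None, :] - sp[None, :, :], axis=2)
    nbr = [np.flatnonzero(dist[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in nbr])
    labels = np.full(n, NOISE)
    c = 0
    for i in range(n):
        if not core[i] or labels[i] != NOISE:
            continue
        labels[i] = c
        stack = [i]
        while stack:
            j = stack.pop()
            for k in nbr[j]:
                if core[k] and labels[k] == NOISE:
                    labels[k] = c
                    stack.append(k)
        c += 1
    for i in range(n):
        if labels[i] != NOISE or core[i]:
            continue
        for k in nbr[i]:  # nbr is sorted ascending
            if core[k]:
                labels[i] = labels[k]
                break
    remap = {}
    for i in range(n):
        if labels[i] != NOISE and labels[i] not in remap:
            remap[labels[i]] = len(remap)
    canon = np.array([remap[v] if v != NOISE else NOISE for v in labels])
    out = np.empty(n, dtype=int)
    out[order] = canon
    return out


def brute_core_points(points, eps: float, min_pts: int) -> set[int]:
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    return {i for i in range(len(pts)) if np.sum(dist[i] <= eps) >= min_pts}


def ks_statistic(x, y) -> float:
    x, y = np.sort(x), np.sort(y)
    pooled = np.concatenate([x, y])
    return float(
        np.max(
            np.abs(
                np.searchsorted(x, pooled, side="right") / len(x)
                - np.searchsorted(y, pooled, side="right") / len(y)
            )
        )
    )


def enumerate_ks_p(x, y) -> float:
    """Exact two-sample KS p-value by exhaustive label enumeration."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    d_obs = ks_statistic(x, y)
    hits = 0
    total = comb(n1 + n2, n1)
    for idx in combinations(range(n1 + n2), n1):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[list(idx)] = True
        if ks_statistic(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def enumerate_mw_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by exhaustive rank enumeration."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1.0  # no ties assumed
    u_obs = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2.0
    hits = total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = float(np.sum(ranks[list(idx)]) - n1 * (n1 + 1) / 2)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


def kruskal_h(groups) -> float:
    """Direct rank formula H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2 (no ties)."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = pooled.argsort().argsort() + 1.0
    edges = np.cumsum([0] + [len(g) for g in groups])
    h = 0.0
    for i in range(len(groups)):
        gr = ranks[edges[i] : edges[i + 1]]
        h += len(gr) * (gr.mean() - (n + 1) / 2.0) ** 2
    return 12.0 / (n * (n + 1)) * h


def min_pixel_gap(pix_a, pix_b, voxel_size: float) -> float:
    """Brute-force all-pairs nearest distance between two pixel sets (nm)."""
    a = np.asarray(pix_a, float) * voxel_size
    b = np.asarray(pix_b, float) * voxel_size
    return float(np.min(np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)))
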