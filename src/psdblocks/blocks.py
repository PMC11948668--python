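"""DBSCAN nanoblock segmentation and morphometrics.

A *nanoblock* is a DBSCAN cluster of dark pixels in the projected PSD slab:
the unit of PSD organization this package quantifies.  The DBSCAN semantics
follow the MATLAB convention used to define the operating point eps = 6 px,
min_pts = 32:

* a point is *core* iff its closed eps-ball contains >= min_pts points,
  counting the point itself;
* clusters are connected components of core points under eps-reachability;
* border points (non-core within eps of a core point) join the cluster of
  the first core point that reaches them in deterministic scan order, after
  pre-sorting all points lexicographically by (u, w) — so the labeling is
  independent of input ordering;
* everything else is noise (label -1).

Cluster ids are canonical: clusters are numbered 0, 1, ... by their smallest
member in scan order.

Morphometric definitions (all in nm):

* area      — convex-hull area of member pixel centers (shoelace);
* width     — largest x-axis (u) distance between two member pixels; the u
  axis is used alone to avoid missing-wedge distortion along the beam axis;
* centroid  — equal-weight mean of member pixel coordinates;
* D         — distance from the centroid to the farthest hull vertex (the
  block "radius" used to normalize alignment distances);
* height    — depth extent of the block beneath the membrane, measured on
  the slice-averaged (u, depth) image at the block's widest column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .errors import BoundsError
from .slab import PixelCloud, _pixel_index
from .volio import MembranePlane, VolumeGrid

__all__ = [
    "DbscanParams",
    "Nanoblock",
    "BlockSetSummary",
    "dbscan",
    "build_nanoblocks",
    "block_height",
    "block_distances",
    "parameter_sweep",
    "NOISE",
]

NOISE = -1


@dataclass(frozen=True)
class DbscanParams:
    """DBSCAN operating point: Euclidean metric on (u, w) pixel coordinates.

    ``min_pts`` counts the query point itself (MATLAB convention).  The
    study operating point for synaptosome-type data is eps = 6 px,
    min_pts = 32.
    """

    eps: float = 6.0
    min_pts: int = 32

    def __post_init__(self):
        if not self.eps > 0:
            raise ValueError(f"eps must be > 0, got {self.eps}")
        if self.min_pts < 1:
            raise ValueError(f"min_pts must be >= 1, got {self.min_pts}")


@dataclass
class Nanoblock:
    """One PSD nanoblock with its hull and morphometrics (coordinates in nm)."""

    id: int
    pixels: np.ndarray  # member (u, w) plane pixel indices, int
    pixel_size: float
    centroid: np.ndarray  # nm
    hull: np.ndarray  # hull vertices, nm, CCW
    area: float  # nm^2
    width: float  # nm
    D: float  # nm
    height: float | None = None
    type_label: str = "unassigned"

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def pixels_nm(self) -> np.ndarray:
        return self.pixels.astype(float) * self.pixel_size


@dataclass
class BlockSetSummary:
    """Per-block morphometrics table plus nearest-neighbor distance tables."""

    table: pd.DataFrame
    distances: pd.DataFrame = field(default_factory=pd.DataFrame)


def dbscan(points: np.ndarray, params: DbscanParams) -> np.ndarray:
    """Cluster 2D points; returns one label per input point (noise = -1).

    Implements the semantics documented at module level.  Duplicates are
    allowed.  Empty input yields an empty labeling.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        return np.empty(0, dtype=int)
    order = np.lexsort((pts[:, 1], pts[:, 0]))  # by u, then w
    sp = pts[order]
    tree = cKDTree(sp)
    neighbors = tree.query_ball_point(sp, params.eps)
    core = np.array([len(nb) >= params.min_pts for nb in neighbors])

    labels = np.full(n, NOISE, dtype=int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != NOISE:
            continue
        labels[i] = cluster
        stack = [i]
        while stack:
            j = stack.pop()
            for k in neighbors[j]:
                if core[k] and labels[k] == NOISE:
                    labels[k] = cluster
                    stack.append(k)
        cluster += 1
    # border points: first core neighbor in scan order decides
    for i in range(n):
        if labels[i] != NOISE or core[i]:
            continue
        for k in sorted(neighbors[i]):
            if core[k]:
                labels[i] = labels[k]
                break
    # canonical renumbering by smallest member in scan order
    remap: dict[int, int] = {}
    for i in range(n):
        c = labels[i]
        if c != NOISE and c not in remap:
            remap[c] = len(remap)
    canon = np.array([remap[c] if c != NOISE else NOISE for c in labels])
    out = np.empty(n, dtype=int)
    out[order] = canon
    return out


def _hull_of(pix_nm: np.ndarray) -> tuple[np.ndarray, float]:
    """Convex hull vertices (CCW, nm) and shoelace area; degenerate-safe."""
    uniq = np.unique(pix_nm, axis=0)
    if len(uniq) == 1:
        return uniq.copy(), 0.0
    try:
        hull = ConvexHull(uniq)
        verts = uniq[hull.vertices]
    except QhullError:
        # collinear cluster: hull is the segment between extreme points
        centered = uniq - uniq.mean(axis=0)
        direction = centered[np.argmax(np.linalg.norm(centered, axis=1))]
        t = centered @ direction
        verts = np.array([uniq[np.argmin(t)], uniq[np.argmax(t)]])
    # shoelace on the vertex polygon (0 for <3 vertices)
    if len(verts) < 3:
        return verts, 0.0
    x, y = verts[:, 0], verts[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return verts, float(area)


def build_nanoblocks(
    cloud: PixelCloud, labels: np.ndarray, voxel_size: float | None = None
) -> list[Nanoblock]:
    """Turn DBSCAN labels over a pixel cloud into Nanoblock records.

    One block per non-noise cluster id, in ascending id order.  ``voxel_size``
    defaults to the cloud's source projection pixel size.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cloud.pixels):
        raise ValueError("labels must align 1:1 with cloud pixels")
    vs = float(voxel_size) if voxel_size is not None else cloud.pixel_size
    blocks: list[Nanoblock] = []
    for cid in np.unique(labels[labels != NOISE]):
        pix = cloud.pixels[labels == cid]
        pix_nm = pix.astype(float) * vs
        centroid = pix_nm.mean(axis=0)
        hull, area = _hull_of(pix_nm)
        width = float((pix[:, 0].max() - pix[:, 0].min()) * vs)
        ref = hull if len(hull) >= 2 else pix_nm
        D = float(np.max(np.linalg.norm(ref - centroid, axis=1)))
        blocks.append(
            Nanoblock(
                id=int(cid),
                pixels=pix,
                pixel_size=vs,
                centroid=centroid,
                hull=hull,
                area=area,
                width=width,
                D=D,
            )
        )
    return blocks


def block_height(
    volume: VolumeGrid,
    block: Nanoblock,
    membrane: MembranePlane,
    background: float,
    max_depth: float = 40.0,
) -> float | None:
    """Depth extent of a nanoblock beneath the membrane, in nm.

    The volume is averaged over the block's w (slice) extent into a 2D
    (u, depth) image; at the u column where the block has the most member
    pixels (its largest extent; ties -> smallest u), the contiguous run of
    below-background depth bins starting at the membrane is measured.  The
    height is the outer edge of the last bin in that run.  Returns ``None``
    (undefined, to be flagged) when no below-background bin adjoins the
    membrane.
    """
    if block.n_pixels == 0:
        raise ValueError("block has no member pixels")
    vs = volume.voxel_size
    n = membrane.normal
    u_axis, _w_axis = membrane.basis
    cx, cy, cz = (volume.voxel_centers_1d(a) for a in range(3))
    rel = -membrane.point
    d = (
        (cx * n[0] + rel @ n)[:, None, None]
        + (cy * n[1])[None, :, None]
        + (cz * n[2])[None, None, :]
    )
    inside = (d > 0) & (d <= max_depth)
    if not np.any(inside):
        raise BoundsError("slab does not intersect the volume")
    uu = (
        (cx * u_axis[0] + rel @ u_axis)[:, None, None]
        + (cy * u_axis[1])[None, :, None]
        + (cz * u_axis[2])[None, None, :]
    )
    w_axis = _w_axis
    ww = (
        (cx * w_axis[0] + rel @ w_axis)[:, None, None]
        + (cy * w_axis[1])[None, :, None]
        + (cz * w_axis[2])[None, None, :]
    )
    au = _pixel_index(uu[inside] / vs)
    aw = _pixel_index(ww[inside] / vs)
    dep = d[inside]
    vals = volume.data[inside].astype(float)

    # restrict to the block's slice (w) extent
    w_lo, w_hi = int(block.pixels[:, 1].min()), int(block.pixels[:, 1].max())
    keep = (aw >= w_lo) & (aw <= w_hi)
    if not np.any(keep):
        raise BoundsError("block footprint lies outside the volume slab")
    au, dep, vals = au[keep], dep[keep], vals[keep]

    # widest u column of the block (most member pixels; ties -> smallest u)
    ucols, counts = np.unique(block.pixels[:, 0], return_counts=True)
    u_star = int(ucols[np.argmax(counts)])
    at_col = au == u_star
    if not np.any(at_col):
        raise BoundsError("block's widest column lies outside the volume")
    dep, vals = dep[at_col], vals[at_col]
    bins = np.floor(dep / vs).astype(np.int64)
    nb = int(bins.max()) + 1
    cnt = np.bincount(bins, minlength=nb)
    mean = np.where(cnt > 0, np.bincount(bins, weights=vals, minlength=nb) / np.maximum(cnt, 1), np.inf)

    if cnt[0] == 0 or mean[0] >= background:
        return None
    last = 0
    while last + 1 < nb and cnt[last + 1] > 0 and mean[last + 1] < background:
        last += 1
    return float((last + 1) * vs)


def block_distances(blocks: list[Nanoblock]) -> pd.DataFrame:
    """Nearest-neighbor centroid-to-centroid and edge-to-edge distances (nm).

    Edge-to-edge distance between two blocks is the minimum pairwise
    distance between their member pixel centers.  With fewer than two
    blocks the table is empty.
    """
    cols = ["block_id", "nn_centroid_nm", "nn_edge_nm"]
    if len(blocks) < 2:
        return pd.DataFrame(columns=cols)
    cents = np.array([b.centroid for b in blocks])
    trees = [cKDTree(b.pixels_nm()) for b in blocks]
    rows = []
    for i, b in enumerate(blocks):
        cd = np.linalg.norm(cents - cents[i], axis=1)
        cd[i] = np.inf
        nn_c = float(cd.min())
        nn_e = np.inf
        for j, other in enumerate(blocks):
            if j == i:
                continue
            dmin = trees[j].query(b.pixels_nm(), k=1)[0].min()
            nn_e = min(nn_e, float(dmin))
        rows.append({"block_id": b.id, "nn_centroid_nm": nn_c, "nn_edge_nm": nn_e})
    return pd.DataFrame(rows, columns=cols)


def parameter_sweep(
    cloud: PixelCloud,
    eps_list,
    min_pts_list,
    voxel_size: float | None = None,
) -> pd.DataFrame:
    """Run DBSCAN + morphometrics over a grid of (eps, min_pts) settings.

    One row per combination with the block count, noise count and an area
    distribution summary — the tool behind choosing an operating point by
    visual consistency, which this package surfaces but does not automate.
    """
    eps_list = list(eps_list)
    min_pts_list = list(min_pts_list)
    if not eps_list or not min_pts_list:
        raise ValueError("eps_list and min_pts_list must be non-empty")
    rows = []
    for eps in eps_list:
        for mp in min_pts_list:
            labels = dbscan(cloud.pixels, DbscanParams(eps=eps, min_pts=mp))
            blocks = build_nanoblocks(cloud, labels, voxel_size)
            areas = np.array([b.area for b in blocks])
            rows.append(
                {
                    "eps": eps,
                    "min_pts": mp,
                    "n_blocks": len(blocks),
                    "n_noise": int(np.sum(labels == NOISE)),
                    "area_median_nm2": float(np.median(areas)) if len(areas) else np.nan,
                    "area_q25_nm2": float(np.quantile(areas, 0.25)) if len(areas) else np.nan,
                    "area_q75_nm2": float(np.quantile(areas, 0.75)) if len(areas) else np.nan,
                    "area_total_nm2": float(areas.sum()) if len(areas) else 0.0,
                }
            )
    return pd.DataFrame(rows)
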