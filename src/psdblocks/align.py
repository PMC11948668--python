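"""Alignment of receptor-like particles and vesicles with PSD nanoblocks.

Particles and vesicles are annotated in 3D, orthogonally projected into the
membrane plane, and related to nanoblocks through the normalized distance

    ratio = d / D

where ``d`` is the in-plane distance from the point to a block centroid and
``D`` is that block's radius (centroid to farthest hull vertex).  A ratio
below 1 means the point falls "within nanoblock range".  Block-level typing
(A / B / mixed / none) is decided by boundary-inclusive point-in-convex-hull
membership of type A/B particles.

The randomization null re-draws each point uniformly over the eligible PSD
pixel domain (default: pixels inside the convex hull of the union of all
nanoblock member pixels) a fixed number of replicates (default 100), and
recomputes the ratios with the same pairing mode as the experimental
points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .blocks import Nanoblock
from .errors import DegenerateBlockError, InputError
from .volio import MembranePlane

__all__ = [
    "AlignmentRecord",
    "RandomizationNull",
    "project_to_plane",
    "normalized_ratio",
    "pair_points",
    "classify_blocks",
    "point_in_hull",
    "psd_domain",
    "build_randomization_null",
    "fraction_within_range",
    "records_to_frame",
]

PAIRING_MODES = ("nearest_centroid", "all_pairs")


@dataclass
class AlignmentRecord:
    """One (point, block) pairing with its normalized distance."""

    point_id: str
    point_kind: str
    block_id: int
    d: float  # nm, in-plane point-to-centroid distance
    D: float  # nm, block radius
    ratio: float  # d / D
    pairing_mode: str
    block_type: str = "unassigned"


@dataclass
class RandomizationNull:
    """Uniform-over-PSD-pixels randomization of point positions.

    ``ratios[r]`` holds the d/D sample of replicate ``r`` (one value per
    point in nearest_centroid mode; one per point-block pair in all_pairs
    mode).
    """

    domain_pixels: np.ndarray
    reps: int
    seed: int
    mode: str
    ratios: np.ndarray  # (reps, n_ratios_per_rep)
    positions: np.ndarray = field(default=None, repr=False)  # (reps, n_points, 2) nm

    def pooled(self) -> np.ndarray:
        return self.ratios.reshape(-1)


def project_to_plane(points: np.ndarray, membrane: MembranePlane) -> np.ndarray:
    """Orthogonal projection of 3D points (nm) into the (u, w) plane frame."""
    return membrane.to_plane_coords(points)


def normalized_ratio(
    point2d: np.ndarray,
    block: Nanoblock,
    point_id: str = "",
    point_kind: str = "",
    pairing_mode: str = "nearest_centroid",
) -> AlignmentRecord:
    """d/D record for one projected point against one block.

    Raises :class:`DegenerateBlockError` for single-pixel blocks (D = 0);
    such blocks are excluded from ratio analyses upstream.
    """
    if block.D <= 0:
        raise DegenerateBlockError(f"block {block.id} has D = 0; ratio undefined")
    d = float(np.linalg.norm(np.asarray(point2d, dtype=float) - block.centroid))
    return AlignmentRecord(
        point_id=point_id,
        point_kind=point_kind,
        block_id=block.id,
        d=d,
        D=float(block.D),
        ratio=d / float(block.D),
        pairing_mode=pairing_mode,
        block_type=block.type_label,
    )


def pair_points(
    points2d: np.ndarray,
    blocks: list[Nanoblock],
    mode: str = "nearest_centroid",
    point_ids: list[str] | None = None,
    point_kinds: list[str] | None = None,
) -> list[AlignmentRecord]:
    """Pair projected points with nanoblocks.

    ``nearest_centroid``: each point is paired with the block minimizing the
    raw centroid distance d (ties broken by lowest block id); one record per
    point.  ``all_pairs``: one record per (point, block) combination.
    Blocks with D = 0 are excluded (with a warning) before pairing; if none
    remain the result is empty.
    """
    if mode not in PAIRING_MODES:
        raise ValueError(f"unknown pairing mode {mode!r}; allowed: {PAIRING_MODES}")
    pts = np.atleast_2d(np.asarray(points2d, dtype=float))
    if pts.size == 0:
        return []
    eligible = sorted((b for b in blocks if b.D > 0), key=lambda b: b.id)
    n_excluded = len(blocks) - len(eligible)
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} degenerate block(s) with D = 0", stacklevel=2)
    if not eligible:
        warnings.warn("no eligible blocks (all degenerate or empty); no pairings", stacklevel=2)
        return []
    ids = point_ids if point_ids is not None else [str(i) for i in range(len(pts))]
    kinds = point_kinds if point_kinds is not None else [""] * len(pts)
    cents = np.array([b.centroid for b in eligible])
    records: list[AlignmentRecord] = []
    if mode == "nearest_centroid":
        dist = np.linalg.norm(pts[:, None, :] - cents[None, :, :], axis=2)
        best = np.argmin(dist, axis=1)  # first minimum = lowest block id
        for i, bi in enumerate(best):
            records.append(normalized_ratio(pts[i], eligible[bi], ids[i], kinds[i], mode))
    else:
        for i in range(len(pts)):
            for b in eligible:
                records.append(normalized_ratio(pts[i], b, ids[i], kinds[i], mode))
    return records


def point_in_hull(point2d: np.ndarray, hull: np.ndarray, tol: float = 1e-9) -> bool:
    """Boundary-inclusive membership of a point in a convex polygon.

    ``hull`` is the CCW vertex array of a Nanoblock hull (nm).  Degenerate
    hulls (a point or a segment) use distance-to-vertex / distance-to-segment
    within ``tol``.
    """
    p = np.asarray(point2d, dtype=float)
    hull = np.atleast_2d(hull)
    if len(hull) == 1:
        return bool(np.linalg.norm(p - hull[0]) <= tol)
    if len(hull) == 2:
        a, b = hull
        ab = b - a
        t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-300), 0.0, 1.0)
        return bool(np.linalg.norm(p - (a + t * ab)) <= tol)
    v1 = hull
    v2 = np.roll(hull, -1, axis=0)
    cross = (v2[:, 0] - v1[:, 0]) * (p[1] - v1[:, 1]) - (v2[:, 1] - v1[:, 1]) * (p[0] - v1[:, 0])
    return bool(np.all(cross >= -tol))


def classify_blocks(
    blocks: list[Nanoblock], particles2d: np.ndarray, particle_kinds: list[str]
) -> list[Nanoblock]:
    """Assign each block a type label from the particles inside its hull.

    Labels: ``A`` (>=1 type A particle and no B inside), ``B`` (>=1 B, no
    A), ``mixed`` (both), ``none`` (neither).  Membership is
    boundary-inclusive.  Blocks are modified in place and returned.
    """
    pts = np.atleast_2d(np.asarray(particles2d, dtype=float)) if len(particles2d) else np.empty((0, 2))
    kinds = list(particle_kinds)
    if len(pts) != len(kinds):
        raise ValueError("particles2d and particle_kinds must align")
    for b in blocks:
        has_a = has_b = False
        for p, k in zip(pts, kinds):
            if k not in ("particle_A", "particle_B"):
                continue
            if point_in_hull(p, b.hull):
                if k == "particle_A":
                    has_a = True
                else:
                    has_b = True
        b.type_label = "mixed" if (has_a and has_b) else "A" if has_a else "B" if has_b else "none"
    return blocks


def psd_domain(blocks: list[Nanoblock], mode: str = "hull") -> np.ndarray:
    """Eligible pixel set for the randomization null ("the PSD bounds").

    ``hull`` (default): all integer plane pixels inside the convex hull of
    the union of nanoblock member pixels, boundary inclusive.  ``pixels``:
    the union of the member pixels themselves.
    """
    if not blocks:
        raise InputError("cannot build a PSD domain from zero blocks")
    union = np.unique(np.vstack([b.pixels for b in blocks]), axis=0)
    if mode == "pixels":
        return union
    if mode != "hull":
        raise ValueError(f"unknown domain mode {mode!r}; allowed: 'hull', 'pixels'")
    pts = union.astype(float)
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except QhullError:
        return union  # degenerate PSD (collinear); fall back to the pixels
    lo = union.min(axis=0)
    hi = union.max(axis=0)
    aa, bb = np.meshgrid(
        np.arange(lo[0], hi[0] + 1), np.arange(lo[1], hi[1] + 1), indexing="ij"
    )
    grid = np.column_stack([aa.ravel(), bb.ravel()]).astype(float)
    v1 = verts
    v2 = np.roll(verts, -1, axis=0)
    # vectorized CCW half-plane test, boundary inclusive
    cross = (v2[:, 0] - v1[:, 0])[None, :] * (grid[:, 1:2] - v1[:, 1][None, :]) - (
        v2[:, 1] - v1[:, 1]
    )[None, :] * (grid[:, 0:1] - v1[:, 0][None, :])
    inside = np.all(cross >= -1e-9, axis=1)
    return grid[inside].astype(np.int64)


def build_randomization_null(
    points2d: np.ndarray,
    domain_pixels: np.ndarray,
    blocks: list[Nanoblock],
    reps: int = 100,
    seed: int = 0,
    mode: str = "nearest_centroid",
    pixel_size: float = 1.0,
) -> RandomizationNull:
    """Randomize point positions uniformly over the PSD pixel domain.

    Each of ``reps`` replicates re-draws every point independently and
    uniformly over ``domain_pixels`` (with replacement across points) and
    recomputes d/D with the *same* pairing mode as the experimental
    analysis.  Deterministic given ``seed``.
    """
    domain = np.asarray(domain_pixels)
    if domain.size == 0:
        raise InputError("randomization domain is empty")
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    pts = np.atleast_2d(np.asarray(points2d, dtype=float))
    n_pts = len(pts)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(domain), size=(reps, n_pts))
    positions = domain[idx].astype(float) * pixel_size
    all_ratios = []
    for r in range(reps):
        recs = pair_points(positions[r], blocks, mode=mode)
        all_ratios.append([rec.ratio for rec in recs])
    return RandomizationNull(
        domain_pixels=domain,
        reps=reps,
        seed=seed,
        mode=mode,
        ratios=np.array(all_ratios),
        positions=positions,
    )


def fraction_within_range(records_or_ratios) -> tuple[float, int, int]:
    """Proportion of ratios strictly below 1 ("within nanoblock range").

    Accepts AlignmentRecords or a ratio array; returns ``(proportion,
    n_within, n_total)``.  Empty input is an error (undefined proportion).
    """
    if len(records_or_ratios) == 0:
        raise InputError("proportion undefined for empty input")
    first = records_or_ratios[0] if not isinstance(records_or_ratios, np.ndarray) else None
    if isinstance(first, AlignmentRecord):
        ratios = np.array([r.ratio for r in records_or_ratios])
    else:
        ratios = np.asarray(records_or_ratios, dtype=float).reshape(-1)
    n_within = int(np.sum(ratios < 1.0))
    return n_within / len(ratios), n_within, len(ratios)


def records_to_frame(records: list[AlignmentRecord]) -> pd.DataFrame:
    """AlignmentRecords as a tidy table (CSV-ready)."""
    cols = ["point_id", "kind", "block_id", "block_type", "d_nm", "D_nm", "ratio", "mode"]
    rows = [
        {
            "point_id": r.point_id,
            "kind": r.point_kind,
            "block_id": r.block_id,
            "block_type": r.block_type,
            "d_nm": r.d,
            "D_nm": r.D,
            "ratio": r.ratio,
            "mode": r.pairing_mode,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=cols)
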