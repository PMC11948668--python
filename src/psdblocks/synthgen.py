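"""Synthetic synaptosome-like phantoms with known ground truth.

The generator emulates the gray-value structure the downstream pipeline
quantifies, with every planted quantity recorded so recovery is testable:

* a dark membrane band (2 voxels thick, on the extracellular side of the
  nominal membrane plane so the ``(0, depth]`` slab rule excludes it);
* a PSD layer of discrete dense blocks beneath the membrane, each a
  flattened super-ellipsoid blob: an in-plane ellipse footprint (width
  along u, width x aspect along w) whose local depth thins toward the rim
  as t(r) = depth * (1 - r^p)^(1/p) (exponent p = 4 by default; a
  "cylinder" profile with uniform depth is available for exactly piecewise-
  constant test volumes).  Graded rims matter: they give each block a range
  of projected column contrasts, so darkest-fraction thresholding trims
  block rims gracefully instead of deleting whole shallow blocks;
* receptor-like particle annotations (types A / B / undefined) placed on
  the extracellular side at controlled planted d1/D against their
  generating block, and vesicle annotations at controlled d2/D;
* i.i.d. additive Gaussian noise over a constant background gray value.

Block widths follow a two-component Gaussian mixture (defaults near 30 and
55 nm, echoing the bimodal width distribution of synaptosome PSDs) and
block centers are placed by chained rejection sampling: each new block sits
at an edge-to-edge gap ~ N(gap_mean, gap_sd) nm (floored at ``min_gap``,
default 6.6 nm) from a random existing block, so the packing of the layer
is controlled directly through the gap distribution.  The default gap of
18 +/- 4 nm keeps planted blocks separable by DBSCAN at the study operating
point (solid phantom footprints merge across gaps below ~eps); the tight
packing of real PSDs, with single-digit-nm gaps, is reachable by lowering
``gap_mean``, at the cost of deliberate under-segmentation of touching
blocks.

Everything is a pure function of (params, seed): four independent random
streams (layout, particles, vesicles, noise) are spawned from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from shapely.geometry import MultiPoint, Point

from .errors import PlacementError, SchemaError
from .volio import (
    AnnotationSet,
    MembranePlane,
    PointAnnotation,
    VESICLE_STATES,
    VolumeGrid,
)

__all__ = [
    "SynthParams",
    "PlantedBlock",
    "GroundTruth",
    "generate_layout",
    "render_volume",
    "make_annotations",
    "write_ground_truth",
    "read_ground_truth",
    "mixture_median",
    "simulate",
]


@dataclass
class SynthParams:
    """All knobs of the phantom generator (lengths in nm).

    Defaults encode the study conditions the pipeline is exercised under:
    1.32 nm voxels (3.3 A pixels at binning 4), a 40-nm PSD layer, block
    widths from a 0.6*N(30, 5) + 0.4*N(55, 8) mixture, 6.6-nm minimum edge
    gap with N(18, 4) nm typical gaps, contrast 10x the noise sigma.
    """

    volume_shape: tuple[int, int, int] = (160, 80, 160)
    voxel_size: float = 1.32
    background_gray: float = 0.0
    noise_sigma: float = 1.0
    membrane_y: float = 55.0
    membrane_contrast: float = -12.0
    membrane_thickness_vox: int = 2
    n_blocks: int = 7
    block_width_mixture: tuple = ((0.6, 30.0, 5.0), (0.4, 55.0, 8.0))
    block_depth_range: tuple[float, float] = (16.0, 40.0)
    block_contrast: float = -10.0
    block_aspect: float = 0.75
    block_profile: str = "superellipsoid"  # or "cylinder"
    block_edge_exponent: float = 4.0  # superellipsoid exponent p
    min_gap: float = 6.6
    gap_mean: float = 18.0
    gap_sd: float = 4.0
    width_floor: float = 8.0
    particle_spec: dict = field(
        default_factory=lambda: {
            "particle_A": {"count": 13, "ratio_range": (0.0, 0.8)},
            "particle_B": {"count": 6, "ratio_range": (0.8, 1.6)},
            "particle_undefined": {"count": 20, "ratio_range": (0.0, 1.6)},
        }
    )
    particle_offset: float = 7.0  # nm on the extracellular side of the membrane
    vesicle_spec: dict = field(
        default_factory=lambda: {"count": 5, "ratio_range": (0.0, 1.5), "block_types": None}
    )
    vesicle_offset: float = 45.0  # nm on the presynaptic side
    slab_depth: float = 40.0
    seed: int = 0

    def __post_init__(self):
        w = sum(c[0] for c in self.block_width_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {w}")
        lo, hi = self.block_depth_range
        if not (0 <= lo <= hi <= self.slab_depth):
            raise ValueError(f"block_depth_range must lie within [0, {self.slab_depth}]")
        if self.min_gap < 0:
            raise ValueError("min_gap must be >= 0")
        if self.block_contrast >= 0 or self.membrane_contrast >= 0:
            raise ValueError("contrasts must be negative (darker = denser)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be >= 0")
        if self.block_profile not in ("superellipsoid", "cylinder"):
            raise ValueError(f"unknown block_profile {self.block_profile!r}")
        if self.block_edge_exponent <= 0:
            raise ValueError("block_edge_exponent must be > 0")


@dataclass
class PlantedBlock:
    """Ground-truth geometry of one planted nanoblock."""

    id: int
    center: np.ndarray  # (u, w) nm, ellipse center
    width: float  # nm, full extent along u
    depth: float  # nm beneath the membrane
    aspect: float
    pixels: np.ndarray  # footprint plane pixels (N x 2 int, absolute indices)
    centroid: np.ndarray = None  # (u, w) nm, mean of footprint pixel centers
    D: float = 0.0  # nm, centroid to farthest footprint pixel center
    planted_type: str = "none"

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.pixels = np.asarray(self.pixels, dtype=np.int64)


@dataclass
class GroundTruth:
    """Planted geometry + annotations + the generating parameters."""

    blocks: list[PlantedBlock]
    particles: list[dict]  # id, kind, position (3,), block_id, true_ratio
    vesicles: list[dict]  # id, vesicle_state, position (3,), block_id, true_ratio
    params: SynthParams


def mixture_median(mixture) -> float:
    """Numeric median of a Gaussian mixture (root of CDF - 1/2)."""
    mixture = list(mixture)

    def cdf(x):
        return sum(w * norm.cdf(x, m, s) for (w, m, s) in mixture) - 0.5

    lo = min(m - 8 * s for (_, m, s) in mixture)
    hi = max(m + 8 * s for (_, m, s) in mixture)
    return float(brentq(cdf, lo, hi))


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("layout", "particles", "vesicles", "noise")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _first_voxel_depth(membrane_y: float, voxel_size: float) -> float:
    """Depth of the first voxel-center layer strictly beneath the membrane."""
    return (np.floor(membrane_y / voxel_size + 1e-9) + 1) * voxel_size - membrane_y


def _blob_depth_profile(pixels, center, width, aspect, depth, params: SynthParams) -> np.ndarray:
    """Local depth extent t_max (nm) of the blob over the given plane pixels.

    superellipsoid: t_max(r) = depth * (1 - r^p)^(1/p) on the unit-ellipse
    radial coordinate r — a flat-topped blob whose columns thin out toward
    the rim.  cylinder: t_max = depth everywhere inside the ellipse.
    """
    a = width / 2.0
    b = aspect * width / 2.0
    du = pixels[:, 0] * params.voxel_size - center[0]
    dw = pixels[:, 1] * params.voxel_size - center[1]
    r = np.sqrt((du / a) ** 2 + (dw / b) ** 2)
    if params.block_profile == "cylinder":
        return np.where(r <= 1.0, depth, 0.0)
    p = params.block_edge_exponent
    t = np.zeros(len(r))
    inside = r < 1.0
    t[inside] = depth * (1.0 - r[inside] ** p) ** (1.0 / p)
    return t


def _footprint_pixels(center, width, aspect, depth, params: SynthParams) -> np.ndarray:
    """Plane pixels that receive at least one rendered block voxel."""
    vs = params.voxel_size
    a = width / 2.0
    b = aspect * width / 2.0
    cu, cw = center
    lo_u = int(np.floor((cu - a) / vs)) - 1
    hi_u = int(np.ceil((cu + a) / vs)) + 1
    lo_w = int(np.floor((cw - b) / vs)) - 1
    hi_w = int(np.ceil((cw + b) / vs)) + 1
    uu, ww = np.meshgrid(np.arange(lo_u, hi_u + 1), np.arange(lo_w, hi_w + 1), indexing="ij")
    pix = np.column_stack([uu.ravel(), ww.ravel()]).astype(np.int64)
    t_max = _blob_depth_profile(pix, center, width, aspect, depth, params)
    d0 = _first_voxel_depth(params.membrane_y, vs)
    return pix[t_max >= d0]


def _min_gap_nm(pix_a: np.ndarray, pix_b: np.ndarray, voxel_size: float) -> float:
    from scipy.spatial import cKDTree

    tree = cKDTree(pix_b * voxel_size)
    return float(tree.query(pix_a * voxel_size, k=1)[0].min())


def generate_layout(params: SynthParams) -> GroundTruth:
    """Place blocks, particles and vesicles (geometry only, no rendering).

    Deterministic given ``params.seed``.  Raises :class:`PlacementError`
    (reporting the achieved count) when the rejection-sampling budget is
    exhausted before all blocks fit.
    """
    rng_layout = _streams(params.seed)["layout"]
    vs = params.voxel_size
    nx, _ny, nz = params.volume_shape
    # placement region in plane coordinates, with a margin for the widest blocks
    margin = 40.0
    u_lo, u_hi = margin, (nx - 1) * vs - margin
    w_lo, w_hi = margin, (nz - 1) * vs - margin

    blocks: list[PlantedBlock] = []
    max_attempts = 400 * max(params.n_blocks, 1)
    attempts = 0
    # all pairwise gaps respect this floor (>= min_gap); two-sigma truncation
    # of the gap law keeps the tail of near-touching placements out
    placement_floor = max(params.min_gap, params.gap_mean - 2.0 * params.gap_sd)
    while len(blocks) < params.n_blocks:
        if attempts >= max_attempts:
            raise PlacementError(params.n_blocks, len(blocks))
        attempts += 1
        width = _draw_width(rng_layout, params)
        depth = rng_layout.uniform(*params.block_depth_range)
        if not blocks:
            center = np.array([rng_layout.uniform(u_lo, u_hi), rng_layout.uniform(w_lo, w_hi)])
        else:
            # chained placement: new center at a controlled edge gap from a
            # random existing block, along a random direction
            anchor = blocks[rng_layout.integers(len(blocks))]
            theta = rng_layout.uniform(0, 2 * np.pi)
            gap = max(placement_floor, rng_layout.normal(params.gap_mean, params.gap_sd))
            direction = np.array([np.cos(theta), np.sin(theta)])
            h_anchor = _ellipse_support(anchor.width, anchor.aspect, theta)
            h_new = _ellipse_support(width, params.block_aspect, theta)
            center = anchor.center + (h_anchor + h_new + gap) * direction
            if not (u_lo <= center[0] <= u_hi and w_lo <= center[1] <= w_hi):
                continue
        pix = _footprint_pixels(center, width, params.block_aspect, depth, params)
        if len(pix) < 3:
            continue
        if any(_min_gap_nm(pix, b.pixels, vs) < placement_floor for b in blocks):
            continue
        centroid = pix.astype(float).mean(axis=0) * vs
        D = float(np.max(np.linalg.norm(pix.astype(float) * vs - centroid, axis=1)))
        blocks.append(
            PlantedBlock(
                id=len(blocks),
                center=center,
                width=width,
                depth=depth,
                aspect=params.block_aspect,
                pixels=pix,
                centroid=centroid,
                D=D,
            )
        )

    particles = _plant_particles(blocks, params)
    # planted types must exist before vesicles (their spec may target types)
    _assign_planted_types(blocks, particles, vs)
    vesicles = _plant_vesicles(blocks, params)
    return GroundTruth(blocks=blocks, particles=particles, vesicles=vesicles, params=params)


def _ellipse_support(width: float, aspect: float, theta: float) -> float:
    """Extent of the ellipse footprint along direction theta (support function)."""
    a = width / 2.0
    b = aspect * width / 2.0
    return float(np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2))


def _draw_width(rng: np.random.Generator, params: SynthParams) -> float:
    weights = np.array([c[0] for c in params.block_width_mixture])
    comp = rng.choice(len(weights), p=weights / weights.sum())
    _, mean, sd = params.block_width_mixture[comp]
    return float(max(params.width_floor, rng.normal(mean, sd)))


def _plant_particles(blocks: list[PlantedBlock], params: SynthParams) -> list[dict]:
    rng = _streams(params.seed)["particles"]
    out = []
    if not blocks:
        return out
    y = params.membrane_y - params.particle_offset
    for kind in sorted(params.particle_spec):
        spec = params.particle_spec[kind]
        lo, hi = spec["ratio_range"]
        for i in range(spec["count"]):
            b = blocks[rng.integers(len(blocks))]
            ratio = rng.uniform(lo, hi)
            theta = rng.uniform(0, 2 * np.pi)
            uw = b.centroid + ratio * b.D * np.array([np.cos(theta), np.sin(theta)])
            out.append(
                {
                    "id": f"{kind}_{i}",
                    "kind": kind,
                    "position": np.array([uw[0], y, uw[1]]),
                    "block_id": b.id,
                    "true_ratio": float(ratio),
                }
            )
    return out


def _plant_vesicles(blocks: list[PlantedBlock], params: SynthParams) -> list[dict]:
    rng = _streams(params.seed)["vesicles"]
    out = []
    if not blocks:
        return out
    spec = params.vesicle_spec
    lo, hi = spec["ratio_range"]
    allowed_types = spec.get("block_types")
    y = params.membrane_y - params.vesicle_offset
    for i in range(spec["count"]):
        candidates = blocks
        if allowed_types:
            typed = [b for b in blocks if b.planted_type in allowed_types]
            candidates = typed or blocks
        b = candidates[rng.integers(len(candidates))]
        ratio = rng.uniform(lo, hi)
        theta = rng.uniform(0, 2 * np.pi)
        uw = b.centroid + ratio * b.D * np.array([np.cos(theta), np.sin(theta)])
        out.append(
            {
                "id": f"vesicle_{i}",
                "vesicle_state": VESICLE_STATES[int(rng.integers(len(VESICLE_STATES)))],
                "position": np.array([uw[0], y, uw[1]]),
                "block_id": b.id,
                "true_ratio": float(ratio),
            }
        )
    return out


def _assign_planted_types(blocks: list[PlantedBlock], particles: list[dict], voxel_size: float):
    """Planted block typing via shapely (independent of align.classify_blocks)."""
    ab = [(p["kind"], p["position"]) for p in particles if p["kind"] in ("particle_A", "particle_B")]
    for b in blocks:
        poly = MultiPoint([tuple(p) for p in b.pixels.astype(float) * voxel_size]).convex_hull
        has_a = has_b = False
        for kind, pos in ab:
            if poly.covers(Point(pos[0], pos[2])):
                if kind == "particle_A":
                    has_a = True
                else:
                    has_b = True
        b.planted_type = "mixed" if (has_a and has_b) else "A" if has_a else "B" if has_b else "none"


def render_volume(truth: GroundTruth, params: SynthParams | None = None) -> VolumeGrid:
    """Render the phantom volume from a layout.

    Constant background everywhere; the membrane band (``membrane_thickness_vox``
    voxel layers ending at ``membrane_y``, drawn on the extracellular side)
    offset by ``membrane_contrast``; block voxels offset by
    ``block_contrast``; Gaussian noise added last.  Deterministic given the
    seed embedded in the params.
    """
    params = params or truth.params
    rng_noise = _streams(params.seed)["noise"]
    nx, ny, nz = params.volume_shape
    vs = params.voxel_size
    data = np.full((nx, ny, nz), params.background_gray, dtype=np.float64)

    y = np.arange(ny) * vs
    band = (y > params.membrane_y - params.membrane_thickness_vox * vs) & (y <= params.membrane_y)
    data[:, band, :] += params.membrane_contrast

    for b in truth.blocks:
        pix = b.pixels
        ok = (pix[:, 0] >= 0) & (pix[:, 0] < nx) & (pix[:, 1] >= 0) & (pix[:, 1] < nz)
        pix = pix[ok]
        t_max = _blob_depth_profile(pix, b.center, b.width, b.aspect, b.depth, params)
        depths = y - params.membrane_y  # per-layer depth beneath the membrane
        for j in np.flatnonzero((depths > 0) & (depths <= b.depth)):
            sel = t_max >= depths[j]
            data[pix[sel, 0], j, pix[sel, 1]] += params.block_contrast

    if params.noise_sigma > 0:
        data += rng_noise.normal(0.0, params.noise_sigma, size=data.shape)
    return VolumeGrid(data=data.astype(np.float32), voxel_size=vs)


def true_membrane_plane(params: SynthParams) -> MembranePlane:
    return MembranePlane(
        point=np.array([0.0, params.membrane_y, 0.0]), normal=np.array([0.0, 1.0, 0.0])
    )


def make_annotations(truth: GroundTruth, volume_id: str = "synthetic") -> AnnotationSet:
    """Ground truth -> the AnnotationSet the analysis pipeline consumes.

    Membrane points are a 4x4 grid on the true plane; the empty region is an
    extracellular box clear of the membrane band and the PSD slab.
    """
    p = truth.params
    nx, _ny, nz = p.volume_shape
    vs = p.voxel_size
    gx = np.linspace(10.0, (nx - 1) * vs - 10.0, 4)
    gz = np.linspace(10.0, (nz - 1) * vs - 10.0, 4)
    # snap the grid so its centroid is an exact voxel multiple: annotation
    # clicks land on voxels, and an on-grid plane origin keeps the projection
    # pixel frame aligned with the rendering grid
    gx = gx + (np.round(gx.mean() / vs) * vs - gx.mean())
    gz = gz + (np.round(gz.mean() / vs) * vs - gz.mean())
    membrane_points = np.array([[x, p.membrane_y, z] for x in gx for z in gz])
    band_lo = p.membrane_y - p.membrane_thickness_vox * vs
    empty = (
        np.array([10.0, 5.0, 10.0]),
        np.array([(nx - 1) * vs - 10.0, max(6.0, band_lo - 10.0), (nz - 1) * vs - 10.0]),
    )
    pts: list[PointAnnotation] = []
    for prt in truth.particles:
        pts.append(PointAnnotation(id=prt["id"], kind=prt["kind"], position=prt["position"]))
    for v in truth.vesicles:
        pts.append(
            PointAnnotation(
                id=v["id"], kind="vesicle", vesicle_state=v["vesicle_state"], position=v["position"]
            )
        )
    hint = np.array([(nx - 1) * vs / 2, p.membrane_y + 20.0, (nz - 1) * vs / 2])
    return AnnotationSet(
        volume_id=volume_id,
        membrane_points=membrane_points,
        points=pts,
        empty_region=empty,
        psd_side_hint=hint,
    )


def simulate(params: SynthParams) -> tuple[GroundTruth, VolumeGrid, AnnotationSet]:
    """Layout + rendered volume + annotations in one call."""
    truth = generate_layout(params)
    volume = render_volume(truth, params)
    return truth, volume, make_annotations(truth)


# ---------------------------------------------------------------------------
# Ground-truth JSON round-trip
# ---------------------------------------------------------------------------


def write_ground_truth(truth: GroundTruth, path) -> None:
    doc = {
        "params": _params_to_jsonable(truth.params),
        "blocks": [
            {
                "id": b.id,
                "center": b.center.tolist(),
                "width": b.width,
                "depth": b.depth,
                "aspect": b.aspect,
                "pixels": b.pixels.tolist(),
                "centroid": b.centroid.tolist(),
                "D": b.D,
                "planted_type": b.planted_type,
            }
            for b in truth.blocks
        ],
        "particles": [
            {**p, "position": np.asarray(p["position"]).tolist()} for p in truth.particles
        ],
        "vesicles": [
            {**v, "position": np.asarray(v["position"]).tolist()} for v in truth.vesicles
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid ground-truth JSON ({exc})") from exc
    for key in ("params", "blocks", "particles", "vesicles"):
        if key not in doc:
            raise SchemaError(f"{path}: missing ground-truth key {key!r}")
    params = _params_from_jsonable(doc["params"])
    blocks = [
        PlantedBlock(
            id=b["id"],
            center=np.array(b["center"]),
            width=b["width"],
            depth=b["depth"],
            aspect=b["aspect"],
            pixels=np.array(b["pixels"], dtype=np.int64).reshape(-1, 2),
            centroid=np.array(b["centroid"]),
            D=b["D"],
            planted_type=b["planted_type"],
        )
        for b in doc["blocks"]
    ]
    particles = [{**p, "position": np.array(p["position"])} for p in doc["particles"]]
    vesicles = [{**v, "position": np.array(v["position"])} for v in doc["vesicles"]]
    return GroundTruth(blocks=blocks, particles=particles, vesicles=vesicles, params=params)


def _params_to_jsonable(params: SynthParams) -> dict:
    d = asdict(params)
    d["volume_shape"] = list(params.volume_shape)
    d["block_width_mixture"] = [list(c) for c in params.block_width_mixture]
    d["block_depth_range"] = list(params.block_depth_range)
    for spec in d["particle_spec"].values():
        spec["ratio_range"] = list(spec["ratio_range"])
    d["vesicle_spec"]["ratio_range"] = list(d["vesicle_spec"]["ratio_range"])
    return d


def _params_from_jsonable(d: dict) -> SynthParams:
    d = dict(d)
    d["volume_shape"] = tuple(d["volume_shape"])
    d["block_width_mixture"] = tuple(tuple(c) for c in d["block_width_mixture"])
    d["block_depth_range"] = tuple(d["block_depth_range"])
    for spec in d["particle_spec"].values():
        spec["ratio_range"] = tuple(spec["ratio_range"])
    d["vesicle_spec"]["ratio_range"] = tuple(d["vesicle_spec"]["ratio_range"])
    try:
        return SynthParams(**d)
    except TypeError as exc:
        raise SchemaError(f"invalid ground-truth params: {exc}") from exc
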