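"""PSD slab extraction, projection, thresholding, and 1-D density profiles.

The central object is the :class:`SlabProjection`: for every in-plane pixel
``(u, w)`` it holds the *column average* of all voxels whose signed distance
to the postsynaptic membrane plane lies in the half-open interval
``(0, depth]`` on the PSD side.  The open lower bound excludes voxels of the
membrane itself ("beneath the membrane").  Columns are sampled without
interpolation: each voxel center is assigned to the nearest in-plane pixel,
which preserves the gray-value statistics consumed by DBSCAN downstream.

Pixel coordinates are *absolute* plane-frame indices: pixel ``(a, b)``
corresponds to in-plane position ``(a * pixel_size, b * pixel_size)`` nm in
the membrane's (u, w) frame, so indices may be negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .errors import BoundsError, EmptySlabError, FitFailureError
from .volio import MembranePlane, VolumeGrid

__all__ = [
    "SlabProjection",
    "PixelCloud",
    "DensityProfile",
    "extract_slab_projection",
    "estimate_background",
    "threshold_projection",
    "profile_1d",
    "fit_profile_peaks",
    "THRESHOLD_MODES",
]

THRESHOLD_MODES = ("below_background_fraction", "global_fraction", "below_background_percentile")


def _pixel_index(x: np.ndarray) -> np.ndarray:
    """Nearest-pixel index with half-integers rounded consistently upward.

    np.rint rounds halves to even, which merges adjacent columns whenever the
    plane frame origin sits exactly half a pixel off the voxel grid; a
    floor(x + 1/2) rule keeps the voxel-to-pixel map bijective (the 1e-9
    guards against 0.4999... float representations of exact halves).
    """
    return np.floor(x + 0.5 + 1e-9).astype(np.int64)



@dataclass
class SlabProjection:
    """2D map of column-averaged gray values over the PSD slab.

    ``values[a - index_origin[0], b - index_origin[1]]`` is the mean gray
    value of the column at absolute plane pixel ``(a, b)``; pixels with no
    contributing voxel are masked (NaN, ``column_counts == 0``).
    """

    values: np.ndarray
    column_counts: np.ndarray
    pixel_size: float
    depth: float
    membrane: MembranePlane
    index_origin: tuple[int, int]

    @property
    def mask(self) -> np.ndarray:
        """True where the projection is undefined (no contributing voxels)."""
        return self.column_counts == 0

    def pixel_indices(self) -> np.ndarray:
        """Absolute (a, b) indices of all unmasked pixels, lexicographic order."""
        aa, bb = np.nonzero(self.column_counts > 0)
        return np.column_stack([aa + self.index_origin[0], bb + self.index_origin[1]])

    def value_at(self, pixels: np.ndarray) -> np.ndarray:
        px = np.atleast_2d(pixels)
        return self.values[px[:, 0] - self.index_origin[0], px[:, 1] - self.index_origin[1]]

    def pixels_to_nm(self, pixels: np.ndarray) -> np.ndarray:
        return np.atleast_2d(pixels).astype(float) * self.pixel_size


@dataclass
class PixelCloud:
    """The selected darkest-pixel set that is fed to DBSCAN.

    ``pixels`` are absolute plane indices (N x 2 int), sorted
    lexicographically; ``values`` are the corresponding column-averaged gray
    values.
    """

    pixels: np.ndarray
    values: np.ndarray
    background: float
    fraction: float
    mode: str
    source: SlabProjection | None = None
    empty_reason: str | None = None

    def __len__(self) -> int:
        return len(self.pixels)

    @property
    def pixel_size(self) -> float:
        return self.source.pixel_size if self.source is not None else 1.0


@dataclass
class DensityProfile:
    """1-D averaged gray-value profile with optional fitted dip components."""

    positions: np.ndarray
    values: np.ndarray
    fitted_peaks: list[tuple[float, float, float]] = field(default_factory=list)
    baseline: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("profile positions must be strictly increasing")


def extract_slab_projection(
    volume: VolumeGrid, membrane: MembranePlane, depth: float = 40.0
) -> SlabProjection:
    """Column-average the ``(0, depth]`` nm slab beneath the membrane.

    Every voxel center with signed plane distance in ``(0, depth]`` is
    binned to its nearest in-plane pixel (pixel pitch = voxel size); each
    projection pixel is the arithmetic mean of its column.  Raises
    :class:`EmptySlabError` when no voxel falls inside the slab.
    """
    if depth <= 0:
        raise ValueError(f"depth must be > 0, got {depth}")
    vs = volume.voxel_size
    n = membrane.normal
    u_axis, w_axis = membrane.basis
    cx = volume.voxel_centers_1d(0)
    cy = volume.voxel_centers_1d(1)
    cz = volume.voxel_centers_1d(2)

    # Signed distance and in-plane coordinates are separable over the axes.
    rel = -membrane.point
    d = (
        (cx * n[0] + rel @ n)[:, None, None]
        + (cy * n[1])[None, :, None]
        + (cz * n[2])[None, None, :]
    )
    inside = (d > 0) & (d <= depth)
    if not np.any(inside):
        raise EmptySlabError(
            f"slab (0, {depth}] nm beneath the membrane does not intersect the volume"
        )
    uu = (
        (cx * u_axis[0] + rel @ u_axis)[:, None, None]
        + (cy * u_axis[1])[None, :, None]
        + (cz * u_axis[2])[None, None, :]
    )[inside]
    ww = (
        (cx * w_axis[0] + rel @ w_axis)[:, None, None]
        + (cy * w_axis[1])[None, :, None]
        + (cz * w_axis[2])[None, None, :]
    )[inside]
    vals = volume.data[inside].astype(float)

    au = _pixel_index(uu / vs)
    aw = _pixel_index(ww / vs)
    a0, b0 = int(au.min()), int(aw.min())
    nu = int(au.max()) - a0 + 1
    nw = int(aw.max()) - b0 + 1
    flat = (au - a0) * nw + (aw - b0)
    counts = np.bincount(flat, minlength=nu * nw).reshape(nu, nw)
    sums = np.bincount(flat, weights=vals, minlength=nu * nw).reshape(nu, nw)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return SlabProjection(
        values=values,
        column_counts=counts,
        pixel_size=vs,
        depth=float(depth),
        membrane=membrane,
        index_origin=(a0, b0),
    )


def estimate_background(volume: VolumeGrid, empty_region) -> float:
    """Mean gray value over an axis-aligned box of empty space (ice).

    ``empty_region`` is ``(min_corner_nm, max_corner_nm)``.  Voxels whose
    centers fall inside the box are averaged.  A box entirely outside the
    volume raises :class:`BoundsError`.
    """
    lo = np.asarray(empty_region[0], dtype=float)
    hi = np.asarray(empty_region[1], dtype=float)
    sel = []
    for axis in range(3):
        c = volume.voxel_centers_1d(axis)
        sel.append((c >= lo[axis]) & (c <= hi[axis]))
    if not (sel[0].any() and sel[1].any() and sel[2].any()):
        raise BoundsError(f"empty_region {lo}..{hi} nm lies outside the volume")
    box = volume.data[np.ix_(sel[0], sel[1], sel[2])]
    if box.size < 100:
        import warnings

        warnings.warn(
            f"background box contains only {box.size} voxels; the estimate is noisy",
            stacklevel=2,
        )
    return float(box.mean())


def threshold_projection(
    projection: SlabProjection,
    background: float,
    fraction: float,
    mode: str = "below_background_fraction",
) -> PixelCloud:
    """Select the darkest pixel fraction of the projection.

    ``below_background_fraction`` (the primary rule): candidates are unmasked
    pixels strictly darker than ``background``; the ``floor(fraction * n)``
    darkest candidates are kept.  ``global_fraction``: same selection over
    all unmasked pixels (for normalized maps with no meaningful background).
    ``below_background_percentile`` (alternative reading, kept as an option):
    keep below-background pixels at or below the ``fraction`` quantile of the
    below-background values.

    Ties in gray value are broken by lexicographic (u, w) pixel order, so the
    selection is fully deterministic.  An empty candidate set is *not* an
    error: an empty cloud is returned with ``empty_reason`` set.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if mode not in THRESHOLD_MODES:
        raise ValueError(f"unknown threshold mode {mode!r}; allowed: {THRESHOLD_MODES}")
    if mode != "global_fraction" and not math.isfinite(background):
        raise ValueError("background must be finite in below-background modes")

    pixels = projection.pixel_indices()  # lexicographically sorted
    values = projection.value_at(pixels)
    if mode in ("below_background_fraction", "below_background_percentile"):
        cand = values < background
    else:
        cand = np.ones(len(values), dtype=bool)
    cpix, cval = pixels[cand], values[cand]

    def _empty(reason: str) -> PixelCloud:
        return PixelCloud(
            pixels=np.empty((0, 2), dtype=np.int64),
            values=np.empty(0),
            background=background,
            fraction=fraction,
            mode=mode,
            source=projection,
            empty_reason=reason,
        )

    if len(cpix) == 0:
        return _empty("no candidate pixels")

    if mode == "below_background_percentile":
        thr = float(np.quantile(cval, fraction))
        keep = cval <= thr
        sel = np.flatnonzero(keep)
    else:
        n_sel = int(math.floor(fraction * len(cpix)))
        if n_sel == 0:
            return _empty("fraction selects zero pixels")
        # stable sort by value; candidate order is already lexicographic (u, w)
        order = np.argsort(cval, kind="stable")
        sel = order[:n_sel]
    spix, sval = cpix[sel], cval[sel]
    lex = np.lexsort((spix[:, 1], spix[:, 0]))
    return PixelCloud(
        pixels=spix[lex],
        values=sval[lex],
        background=background,
        fraction=fraction,
        mode=mode,
        source=projection,
    )


def profile_1d(
    projection: SlabProjection,
    u_range: tuple[float, float] | None = None,
    w_range: tuple[float, float] | None = None,
    axis: str = "u",
) -> DensityProfile:
    """Average the projection across the transverse extent of a band.

    ``axis`` names the coordinate *along* which the profile runs; the mean
    is taken over the other coordinate within the given nm ranges (full
    extent when a range is None).  Masked pixels are ignored.
    """
    if axis not in ("u", "w"):
        raise ValueError("axis must be 'u' or 'w'")
    vs = projection.pixel_size
    a0, b0 = projection.index_origin
    nu, nw = projection.values.shape
    u_coords = (a0 + np.arange(nu)) * vs
    w_coords = (b0 + np.arange(nw)) * vs
    usel = np.ones(nu, bool) if u_range is None else (u_coords >= u_range[0]) & (u_coords <= u_range[1])
    wsel = np.ones(nw, bool) if w_range is None else (w_coords >= w_range[0]) & (w_coords <= w_range[1])
    if not (usel.any() and wsel.any()):
        raise BoundsError("profile region does not intersect the projection")
    sub = projection.values[np.ix_(usel, wsel)]
    cnt = projection.column_counts[np.ix_(usel, wsel)]
    if axis == "u":
        positions = u_coords[usel]
        transverse = 1
    else:
        positions = w_coords[wsel]
        sub, cnt = sub.T, cnt.T
        transverse = 1
    with np.errstate(invalid="ignore"):
        vals = np.nansum(np.where(cnt > 0, sub, 0.0), axis=transverse)
        nn = (cnt > 0).sum(axis=transverse)
    good = nn > 0
    if not good.any():
        raise BoundsError("profile region contains only masked pixels")
    return DensityProfile(positions=positions[good], values=vals[good] / nn[good])


# ---------------------------------------------------------------------------
# Sum-of-Gaussians dip fitting
# ---------------------------------------------------------------------------


def _gauss_model(x: np.ndarray, params: np.ndarray, k: int) -> np.ndarray:
    y = np.full_like(x, params[0], dtype=float)
    for i in range(k):
        amp, mu, sd = params[1 + 3 * i : 4 + 3 * i]
        y += amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return y


def fit_gaussian_peaks(
    x: np.ndarray, y: np.ndarray, max_components: int = 5
) -> tuple[list[tuple[float, float, float]], float]:
    """Least-squares constant + sum-of-Gaussians fit with BIC model selection.

    Fits positive peaks on ``y``; the number of components ``k`` in
    ``0..max_components`` is chosen by BIC.  Returns ``(peaks, baseline)``
    where peaks are ``(center, sd, amplitude)`` sorted by center.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 8:
        raise ValueError("need at least 8 samples for peak fitting")
    n = len(x)
    dx = float(np.median(np.diff(x)))
    span = float(x[-1] - x[0])

    def bic(rss: float, n_par: int) -> float:
        rss = max(rss, 1e-300)
        return n * math.log(rss / n) + n_par * math.log(n)

    base = float(np.mean(y))
    best = {"k": 0, "params": np.array([base]), "bic": bic(float(np.sum((y - base) ** 2)), 1)}

    resid = y - base
    prom = max(1e-12, 0.05 * (y.max() - y.min()))
    peak_idx, _ = signal.find_peaks(resid, prominence=prom)
    # seed order: tallest residual peaks first, then greedy residual maxima
    peak_idx = list(peak_idx[np.argsort(resid[peak_idx])[::-1]])

    params = np.array([base])
    last_fail = None
    for k in range(1, max_components + 1):
        model_resid = y - _gauss_model(x, params, k - 1)
        if len(peak_idx) >= k:
            seed_i = peak_idx[k - 1]
        else:
            seed_i = int(np.argmax(model_resid))
        amp0 = max(model_resid[seed_i], prom)
        p0 = np.concatenate([params, [amp0, x[seed_i], max(2 * dx, span / 20)]])
        lo = np.concatenate([[-np.inf], np.tile([0.0, x[0] - span, dx / 2], k)])
        hi = np.concatenate([[np.inf], np.tile([np.inf, x[-1] + span, 2 * span], k)])
        try:
            res = optimize.least_squares(
                lambda p: _gauss_model(x, p, k) - y,
                np.clip(p0, lo, hi),
                bounds=(lo, hi),
                max_nfev=2000,
            )
        except Exception as exc:  # numerical failure inside the optimizer
            last_fail = exc
            break
        rss = float(np.sum(res.fun**2))
        b = bic(rss, 1 + 3 * k)
        if b < best["bic"] - 1e-9:
            best = {"k": k, "params": res.x, "bic": b}
        params = res.x
    if best["k"] == 0 and last_fail is not None and max_components > 0:
        raise FitFailureError(f"peak fit did not converge: {last_fail}", best=best)
    peaks = []
    p = best["params"]
    for i in range(best["k"]):
        amp, mu, sd = p[1 + 3 * i : 4 + 3 * i]
        if amp > 1e-9 * max(1.0, abs(p[0])) + 1e-12:
            peaks.append((float(mu), float(abs(sd)), float(amp)))
    peaks.sort(key=lambda t: t[0])
    return peaks, float(p[0])


def fit_profile_peaks(profile: DensityProfile, max_components: int = 5) -> DensityProfile:
    """Fit dark dips in a gray-value profile as Gaussian components.

    The profile is negated (protein density positive) and fitted with a
    constant baseline plus up to ``max_components`` Gaussians; the component
    count is chosen by BIC.  Returns a new profile with ``fitted_peaks`` =
    ``(center_nm, sd_nm, amplitude)`` sorted by center (amplitudes are in
    density-positive units, i.e. depth of the dip).
    """
    peaks, baseline = fit_gaussian_peaks(profile.positions, -profile.values, max_components)
    return DensityProfile(
        positions=profile.positions,
        values=profile.values,
        fitted_peaks=peaks,
        baseline=-baseline,
    )
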