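"""Volume and annotation I/O, coordinate conventions, and membrane-plane model.

Conventions used throughout the package
---------------------------------------
* Volumes are stored as ``data[x, y, z]`` with ``z`` the tomographic
  slice axis.  For well-oriented tomograms the membrane normal is close to
  the ``y`` axis, matching the usual projection of the postsynaptic density
  (PSD) onto the *xz* plane; tilted membranes are supported through the
  fitted :class:`MembranePlane`.
* Voxel indices are 0-based.  Physical coordinates are in nanometres and are
  measured at voxel centers: voxel ``(i, j, k)`` sits at
  ``origin + (i, j, k) * voxel_size``.
* Annotation coordinates are always physical (nm), never voxel indices, so
  they are independent of binning.

MRC support
-----------
Volumes are read and written as MRC2014 files (the de-facto container for
tomograms): mode 2 (float32) is written; modes 0/1/2/6 are read.  The MRC
raster is stored section-major ``(z, y, x)``; it is transposed to the
package's ``(x, y, z)`` order on read and back on write.  Only cubic voxels
are supported — anisotropic headers raise :class:`UnsupportedVolumeError`
naming the three pixel sizes.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    BoundsError,
    InsufficientMembraneError,
    MrcFormatError,
    SchemaError,
    UnsupportedVolumeError,
)

__all__ = [
    "VolumeGrid",
    "MembranePlane",
    "PointAnnotation",
    "AnnotationSet",
    "read_volume",
    "write_volume",
    "read_annotations",
    "write_annotations",
    "fit_membrane_plane",
    "PARTICLE_KINDS",
    "VESICLE_STATES",
]

PARTICLE_KINDS = ("particle_A", "particle_B", "particle_undefined", "vesicle")
VESICLE_STATES = ("docked", "tethered", "partially_fused")

_MODE_DTYPES = {
    0: np.dtype("<i1"),
    1: np.dtype("<i2"),
    2: np.dtype("<f4"),
    6: np.dtype("<u2"),
}


@dataclass
class VolumeGrid:
    """A 3D scalar gray-value grid with physical voxel size.

    Gray values are in arbitrary density units with *darker = denser
    protein*, the native cryo-ET convention.

    Parameters
    ----------
    data :
        3D array indexed ``[x, y, z]``.
    voxel_size :
        Isotropic voxel edge length in nm (> 0).
    origin :
        Physical position (nm) of the center of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume data must be 3D with all dims >= 1, got shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite gray values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_centers_1d(self, axis: int) -> np.ndarray:
        """Physical center coordinates (nm) of voxels along one axis."""
        n = self.data.shape[axis]
        return self.origin[axis] + np.arange(n) * self.voxel_size

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) physical corner of the voxel-center bounding box."""
        lo = self.origin.copy()
        hi = self.origin + (np.array(self.shape) - 1) * self.voxel_size
        return lo, hi

    def contains(self, positions: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask: which positions lie within the voxel-center bounds."""
        pts = np.atleast_2d(np.asarray(positions, dtype=float))
        lo, hi = self.bounds()
        return np.all((pts >= lo - tol) & (pts <= hi + tol), axis=1)


@dataclass
class MembranePlane:
    """The postsynaptic membrane reference surface.

    ``normal`` is a unit vector pointing from the membrane into the
    postsynaptic cytoplasm, i.e. toward the PSD, so the PSD slab lies at
    *positive* signed distance.

    The in-plane frame ``(u, w)`` shared with the slab projection is
    constructed deterministically: ``u`` is the projection of the volume
    x-axis onto the plane and ``w`` completes an orthonormal basis, flipped
    if necessary so that it points along positive volume ``z``.
    """

    point: np.ndarray
    normal: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        nrm = np.linalg.norm(self.normal)
        if abs(nrm - 1.0) > 1e-9:
            if nrm == 0:
                raise ValueError("membrane normal must be non-zero")
            self.normal = self.normal / nrm

    @property
    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal in-plane axes (u_axis, w_axis)."""
        n = self.normal
        x_hat = np.array([1.0, 0.0, 0.0])
        u = x_hat - np.dot(x_hat, n) * n
        if np.linalg.norm(u) < 1e-8:
            # normal is (anti)parallel to x; seed u from the y axis instead
            y_hat = np.array([0.0, 1.0, 0.0])
            u = y_hat - np.dot(y_hat, n) * n
        u = u / np.linalg.norm(u)
        w = np.cross(n, u)
        if np.dot(w, [0.0, 0.0, 1.0]) < 0:
            w = -w
        return u, w

    def signed_distance(self, positions: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(positions, dtype=float))
        d = (pts - self.point) @ self.normal
        return d if d.size > 1 else d.reshape(-1)

    def to_plane_coords(self, positions: np.ndarray) -> np.ndarray:
        """Project positions into the (u, w) in-plane frame (nm, Nx2)."""
        pts = np.atleast_2d(np.asarray(positions, dtype=float))
        u_axis, w_axis = self.basis
        rel = pts - self.point
        return np.column_stack([rel @ u_axis, rel @ w_axis])


@dataclass
class PointAnnotation:
    """A single annotated 3D point: a receptor-like particle or a vesicle."""

    id: str
    kind: str
    position: np.ndarray
    vesicle_state: str | None = None

    def __post_init__(self):
        if self.kind not in PARTICLE_KINDS:
            raise SchemaError(f"unknown annotation kind {self.kind!r}; allowed: {PARTICLE_KINDS}")
        if self.vesicle_state is not None and self.vesicle_state not in VESICLE_STATES:
            raise SchemaError(
                f"unknown vesicle_state {self.vesicle_state!r}; allowed: {VESICLE_STATES}"
            )
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class AnnotationSet:
    """All annotations attached to one tomogram."""

    volume_id: str
    membrane_points: np.ndarray
    points: list[PointAnnotation]
    empty_region: tuple[np.ndarray, np.ndarray] | None = None
    psd_side_hint: np.ndarray | None = None

    def __post_init__(self):
        self.membrane_points = np.asarray(self.membrane_points, dtype=float)
        _check_membrane_points(self.membrane_points)
        if self.psd_side_hint is not None:
            self.psd_side_hint = np.asarray(self.psd_side_hint, dtype=float)

    def of_kind(self, *kinds: str) -> list[PointAnnotation]:
        return [p for p in self.points if p.kind in kinds]


def _check_membrane_points(pts: np.ndarray) -> None:
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise InsufficientMembraneError(
            f"need >= 3 membrane points of dimension 3, got array of shape {pts.shape}"
        )
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    # rank < 2 means all points (anti)collinear: the plane is underdetermined
    if s[1] <= max(1e-9, 1e-12 * s[0]):
        raise InsufficientMembraneError("membrane points are collinear; plane underdetermined")


# ---------------------------------------------------------------------------
# MRC2014 I/O
# ---------------------------------------------------------------------------

_HEADER_SIZE = 1024
_MAP_MAGIC = b"MAP "
_MACHST_LE = b"\x44\x44\x00\x00"


def read_volume(path) -> VolumeGrid:
    """Read an MRC2014 volume into package ``(x, y, z)`` order.

    The header pixel size (Å) is converted to nm.  Modes 0/1/2/6 are
    accepted; axis correspondence must be the standard ``mapc,mapr,maps =
    1,2,3``.

    Raises
    ------
    MrcFormatError
        Malformed header or truncated payload.
    UnsupportedVolumeError
        Anisotropic voxels (the message names all three pixel sizes) or a
        non-standard axis correspondence.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise MrcFormatError(f"{path}: file shorter than the 1024-byte MRC header")
    ints = np.frombuffer(raw[:_HEADER_SIZE], dtype="<i4")
    flts = np.frombuffer(raw[:_HEADER_SIZE], dtype="<f4")
    nx, ny, nz, mode = (int(v) for v in ints[:4])
    mx, my, mz = (int(v) for v in ints[7:10])
    cella = flts[10:13]
    mapc, mapr, maps = (int(v) for v in ints[16:19])
    nsymbt = int(ints[23])
    origin_a = flts[49:52]
    magic = raw[208:212]

    if magic != _MAP_MAGIC:
        raise MrcFormatError(f"{path}: missing 'MAP ' magic (got {magic!r}); not MRC2014")
    if mode not in _MODE_DTYPES:
        raise MrcFormatError(f"{path}: unsupported MRC mode {mode} (supported: 0, 1, 2, 6)")
    if min(nx, ny, nz) < 1 or min(mx, my, mz) < 1:
        raise MrcFormatError(f"{path}: non-positive dimensions in header")
    if (mapc, mapr, maps) != (1, 2, 3):
        raise UnsupportedVolumeError(
            f"{path}: non-standard axis correspondence mapc,mapr,maps = {(mapc, mapr, maps)}"
        )

    px = np.array([cella[0] / mx, cella[1] / my, cella[2] / mz])  # Å
    if np.any(px <= 0):
        raise MrcFormatError(f"{path}: non-positive pixel size in header (cella={tuple(cella)})")
    if (px.max() - px.min()) > 1e-3 * px.mean():
        raise UnsupportedVolumeError(
            f"{path}: anisotropic voxels are unsupported; pixel sizes are "
            f"({px[0]:.6g}, {px[1]:.6g}, {px[2]:.6g}) Å"
        )

    dtype = _MODE_DTYPES[mode]
    count = nx * ny * nz
    start = _HEADER_SIZE + nsymbt
    payload = raw[start : start + count * dtype.itemsize]
    if len(payload) < count * dtype.itemsize:
        raise MrcFormatError(f"{path}: truncated data block ({len(payload)} bytes for {count} voxels)")
    data = np.frombuffer(payload, dtype=dtype).reshape(nz, ny, nx)
    data = np.ascontiguousarray(data.transpose(2, 1, 0))  # -> (x, y, z)
    if mode != 2:
        data = data.astype(np.float32)
    return VolumeGrid(
        data=data,
        voxel_size=float(px[0]) / 10.0,  # Å -> nm
        origin=np.asarray(origin_a, dtype=float) / 10.0,
    )


def write_volume(volume: VolumeGrid, path) -> None:
    """Write a volume as MRC2014 mode 2 (float32), little-endian.

    ``read_volume(write_volume(v))`` reproduces the data bit-exactly for
    float32 volumes.  Non-finite data is rejected before anything is
    written.
    """
    if not np.all(np.isfinite(volume.data)):
        raise ValueError("refusing to write volume with non-finite gray values")
    path = Path(path)
    data = np.asarray(volume.data, dtype="<f4")
    nx, ny, nz = data.shape
    vs_a = volume.voxel_size * 10.0  # nm -> Å
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<10i", header, 0, nx, ny, nz, 2, 0, 0, 0, nx, ny, nz)
    struct.pack_into("<3f", header, 40, nx * vs_a, ny * vs_a, nz * vs_a)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()), float(data.mean()))
    struct.pack_into("<2i", header, 88, 1, 0)  # ispg, nsymbt
    struct.pack_into("<3f", header, 196, *(np.asarray(volume.origin) * 10.0))
    header[208:212] = _MAP_MAGIC
    header[212:216] = _MACHST_LE
    struct.pack_into("<f", header, 216, float(data.std()))
    struct.pack_into("<i", header, 220, 1)
    label = b"psdblocks MRC2014 writer"
    header[224 : 224 + len(label)] = label
    try:
        with open(path, "wb") as fh:
            fh.write(bytes(header))
            fh.write(np.ascontiguousarray(data.transpose(2, 1, 0)).tobytes())
    except OSError as exc:
        raise OSError(f"failed to write MRC volume to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["id", "kind", "vesicle_state", "x_nm", "y_nm", "z_nm"]


def read_annotations(path, sidecar=None, volume: VolumeGrid | None = None) -> AnnotationSet:
    """Read the annotation CSV plus its JSON sidecar.

    CSV columns: ``id, kind, vesicle_state, x_nm, y_nm, z_nm``.  The sidecar
    (default: same path with ``.json`` suffix) carries ``volume_id``,
    ``membrane_points`` (list of [x, y, z] nm), ``empty_region``
    ({"min": [...], "max": [...]} nm) and optionally ``psd_side_hint``.

    When a volume is supplied, every annotation position is checked to lie
    inside its bounds.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    df = pd.read_csv(path, comment="#", dtype={"id": str, "kind": str, "vesicle_state": str})
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    points: list[PointAnnotation] = []
    for row_i, row in enumerate(df.itertuples(index=False)):
        if row.kind not in PARTICLE_KINDS:
            raise SchemaError(f"{path} row {row_i}: unknown kind {row.kind!r} (id={row.id!r})")
        state = None if pd.isna(row.vesicle_state) or row.vesicle_state == "" else row.vesicle_state
        points.append(
            PointAnnotation(
                id=str(row.id),
                kind=row.kind,
                vesicle_state=state,
                position=[row.x_nm, row.y_nm, row.z_nm],
            )
        )
    try:
        meta = json.loads(sidecar.read_text())
    except FileNotFoundError:
        raise SchemaError(f"annotation sidecar {sidecar} not found") from None
    except json.JSONDecodeError as exc:
        raise SchemaError(f"annotation sidecar {sidecar}: invalid JSON ({exc})") from exc
    if "membrane_points" not in meta:
        raise SchemaError(f"{sidecar}: missing 'membrane_points'")
    empty_region = None
    if meta.get("empty_region") is not None:
        box = meta["empty_region"]
        empty_region = (np.asarray(box["min"], dtype=float), np.asarray(box["max"], dtype=float))
    aset = AnnotationSet(
        volume_id=str(meta.get("volume_id", path.stem)),
        membrane_points=np.asarray(meta["membrane_points"], dtype=float),
        points=points,
        empty_region=empty_region,
        psd_side_hint=np.asarray(meta["psd_side_hint"], dtype=float)
        if meta.get("psd_side_hint") is not None
        else None,
    )
    if volume is not None and points:
        pos = np.array([p.position for p in points])
        inside = volume.contains(pos)
        if not np.all(inside):
            bad = [points[i].id for i in np.flatnonzero(~inside)]
            raise BoundsError(f"annotations outside volume bounds: {bad}")
    return aset


def write_annotations(aset: AnnotationSet, path, sidecar=None) -> None:
    """Write the CSV + JSON sidecar read back by :func:`read_annotations`."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    rows = []
    for p in aset.points:
        rows.append(
            {
                "id": p.id,
                "kind": p.kind,
                "vesicle_state": p.vesicle_state or "",
                "x_nm": p.position[0],
                "y_nm": p.position[1],
                "z_nm": p.position[2],
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
    meta = {
        "volume_id": aset.volume_id,
        "membrane_points": np.asarray(aset.membrane_points).tolist(),
        "empty_region": None
        if aset.empty_region is None
        else {
            "min": np.asarray(aset.empty_region[0]).tolist(),
            "max": np.asarray(aset.empty_region[1]).tolist(),
        },
        "psd_side_hint": None if aset.psd_side_hint is None else np.asarray(aset.psd_side_hint).tolist(),
    }
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Membrane plane fitting
# ---------------------------------------------------------------------------


def fit_membrane_plane(membrane_points: np.ndarray, psd_side_hint: np.ndarray) -> MembranePlane:
    """Total-least-squares plane through the membrane points.

    Minimizes orthogonal distances (SVD of the centered point cloud).  The
    normal is flipped so that ``psd_side_hint`` — any point known to lie in
    the postsynaptic cytoplasm — has positive signed distance.  The RMS
    orthogonal residual (nm) is stored on the returned plane.
    """
    pts = np.asarray(membrane_points, dtype=float)
    _check_membrane_points(pts)
    hint = np.asarray(psd_side_hint, dtype=float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    d_hint = float(np.dot(hint - centroid, normal))
    if abs(d_hint) < 1e-12:
        raise ValueError("psd_side_hint lies on the fitted plane; orientation ambiguous")
    if d_hint < 0:
        normal = -normal
    residual = float(s[-1] / np.sqrt(len(pts)))
    if residual > 5.0:
        warnings.warn(
            f"membrane plane RMS residual {residual:.2f} nm is large; "
            "check the membrane annotation",
            stacklevel=2,
        )
    return MembranePlane(point=centroid, normal=normal, residual_rms=residual)
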