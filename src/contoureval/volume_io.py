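"""Voxel-grid containers and I/O for binary structure masks and dose grids.

All physical lengths inside the package are centimetres.  File formats that
store millimetres (NIfTI headers, DICOM) are converted at the boundary.
Geometries are axis-aligned: the affine maps voxel index ``i`` to the physical
position of the *center* of voxel ``i``; oblique direction cosines are
rejected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

MM_PER_CM = 10.0


class GeometryError(ValueError):
    """Raised for invalid, mismatched or oblique voxel geometries."""


class ShapeError(ValueError):
    """Raised when a volume is not a 3D array."""


@dataclass(frozen=True)
class ImageGeometry:
    """Axis-aligned voxel grid: shape, spacing (cm/voxel) and origin (cm).

    ``origin`` is the physical position of the center of voxel index
    ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise GeometryError("shape, spacing and origin must be 3-vectors")
        if any(s < 1 for s in self.shape):
            raise GeometryError(f"all shape components must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"all spacing components must be > 0, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cm^3."""
        return float(np.prod(self.spacing))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (cm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices (n,3) to physical cm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Map physical cm coordinates (n,3) to fractional voxel indices."""
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        return (pos - np.asarray(self.origin)) / np.asarray(self.spacing)

    def approx_equal(self, other: "ImageGeometry", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class StructureMask:
    """Binary occupancy of one organ on an :class:`ImageGeometry`.

    ``organ`` is the structure label (e.g. ``M-R``, ``MP-L``); ``provenance``
    records who produced the contour (``manual``, an observer tag, or an
    auto-segmentation method tag).
    """

    geometry: ImageGeometry
    voxels: np.ndarray
    organ: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ShapeError(f"mask must be 3D, got ndim={vox.ndim}")
        if tuple(vox.shape) != self.geometry.shape:
            raise GeometryError(
                f"mask shape {vox.shape} does not match geometry {self.geometry.shape}"
            )
        self.voxels = (vox != 0)

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_cm3(self) -> float:
        """Structure volume: occupied-voxel count x voxel volume."""
        return self.voxel_count * self.geometry.voxel_volume

    def is_empty(self) -> bool:
        return not self.voxels.any()


@dataclass
class DoseGrid:
    """Nonnegative absorbed-dose values (Gy) on an :class:`ImageGeometry`."""

    geometry: ImageGeometry
    dose: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dose, dtype=float)
        if d.ndim != 3:
            raise ShapeError(f"dose grid must be 3D, got ndim={d.ndim}")
        if tuple(d.shape) != self.geometry.shape:
            raise GeometryError(
                f"dose shape {d.shape} does not match geometry {self.geometry.shape}"
            )
        if not np.isfinite(d).all():
            raise ValueError("dose grid contains non-finite values")
        if (d < 0).any():
            raise ValueError("dose grid contains negative values")
        self.dose = d


@dataclass
class StructureSet:
    """All masks of one case, on one shared geometry."""

    case_id: str
    masks: list[StructureMask] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.masks:
            g0 = self.masks[0].geometry
            for m in self.masks[1:]:
                if not m.geometry.approx_equal(g0):
                    raise GeometryError(
                        f"case {self.case_id}: mask {m.organ}/{m.provenance} "
                        "has a different geometry"
                    )

    @property
    def geometry(self) -> ImageGeometry:
        if not self.masks:
            raise ValueError(f"case {self.case_id} has no masks")
        return self.masks[0].geometry

    def add(self, mask: StructureMask) -> None:
        if self.masks and not mask.geometry.approx_equal(self.geometry):
            raise GeometryError("mask geometry differs from the set's geometry")
        self.masks.append(mask)

    def get(self, organ: str, provenance: str) -> StructureMask:
        for m in self.masks:
            if m.organ == organ and m.provenance == provenance:
                return m
        raise KeyError(f"case {self.case_id}: no mask organ={organ!r} provenance={provenance!r}")

    def organs(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.masks:
            seen.setdefault(m.organ)
        return list(seen)

    def provenances(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.masks:
            seen.setdefault(m.provenance)
        return list(seen)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _geometry_from_nifti(img, path, geometry_policy: str) -> ImageGeometry:
    import nibabel  # noqa: F401  (lazy: only needed for file I/O)

    shape = img.shape
    if len(shape) != 3:
        raise ShapeError(f"{path}: expected a 3D volume, got shape {shape}")
    affine = img.affine
    rot = affine[:3, :3]
    # axis-aligned check: one nonzero entry per column
    nonzero = np.abs(rot) > 1e-9
    if not np.array_equal(nonzero.sum(axis=0), [1, 1, 1]) or not np.array_equal(
        nonzero.sum(axis=1), [1, 1, 1]
    ):
        raise GeometryError(
            f"{path}: oblique direction cosines are not supported (axis-aligned only)"
        )
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        if geometry_policy == "strict":
            raise GeometryError(f"{path}: missing or invalid voxel spacing in header")
        warnings.warn(f"{path}: invalid spacing in header, assuming 1 mm", stacklevel=3)
        zooms = tuple(z if np.isfinite(z) and z > 0 else 1.0 for z in zooms)
    spacing_cm = tuple(float(z) / MM_PER_CM for z in zooms)
    origin_cm = tuple(float(o) / MM_PER_CM for o in affine[:3, 3])
    return ImageGeometry(shape=tuple(shape), spacing=spacing_cm, origin=origin_cm)


def read_mask_volume(
    path: str | Path,
    geometry_policy: str = "strict",
    organ: str = "",
    provenance: str = "",
) -> StructureMask:
    """Read a NIfTI binary mask; any nonzero voxel becomes occupied.

    Header spacings (mm) are converted to cm.  ``geometry_policy`` of
    ``"tolerant"`` substitutes 1 mm for missing spacing instead of raising.
    """
    import nibabel as nib

    if geometry_policy not in ("strict", "tolerant"):
        raise ValueError(f"unknown geometry_policy {geometry_policy!r}")
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    geom = _geometry_from_nifti(img, path, geometry_policy)
    data = np.asanyarray(img.dataobj)
    return StructureMask(geometry=geom, voxels=data != 0, organ=organ, provenance=provenance)


def read_dose_volume(path: str | Path, geometry_policy: str = "strict") -> DoseGrid:
    """Read a NIfTI dose grid (Gy values stored as-is)."""
    import nibabel as nib

    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    geom = _geometry_from_nifti(img, path, geometry_policy)
    return DoseGrid(geometry=geom, dose=np.asanyarray(img.dataobj).astype(float))


def _nifti_affine(geometry: ImageGeometry) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(np.asarray(geometry.spacing) * MM_PER_CM)
    affine[:3, 3] = np.asarray(geometry.origin) * MM_PER_CM
    return affine


def write_mask_volume(mask: StructureMask, path: str | Path) -> None:
    """Write a mask as uint8 NIfTI (spacing/origin stored in mm)."""
    import nibabel as nib

    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _nifti_affine(mask.geometry))
    img.header.set_zooms(tuple(s * MM_PER_CM for s in mask.geometry.spacing))
    nib.save(img, str(path))


def write_dose_volume(dose: DoseGrid, path: str | Path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(dose.dose.astype(np.float32), _nifti_affine(dose.geometry))
    img.header.set_zooms(tuple(s * MM_PER_CM for s in dose.geometry.spacing))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Planar-contour rasterization (RT-Struct style input)
# ---------------------------------------------------------------------------

def _points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Vectorized even–odd test; points exactly on an edge count as inside.

    ``poly`` is (k, 2); the polygon is implicitly closed.
    """
    x0 = poly[:, 0]
    y0 = poly[:, 1]
    x1 = np.roll(x0, -1)
    y1 = np.roll(y0, -1)

    px = px[:, None]
    py = py[:, None]

    # on-edge test: collinear and within the segment's bounding box
    ex = x1 - x0
    ey = y1 - y0
    cross = ex * (py - y0) - ey * (px - x0)
    seg_len2 = ex * ex + ey * ey
    dot = (px - x0) * ex + (py - y0) * ey
    on_edge = (
        (np.abs(cross) <= 1e-12 * np.maximum(1.0, np.sqrt(seg_len2)))
        & (dot >= -1e-12)
        & (dot <= seg_len2 + 1e-12)
    ).any(axis=1)

    # even–odd ray crossing (half-open rule avoids double-counting vertices)
    cond = (y0 <= py) != (y1 <= py)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_int = x0 + (py - y0) * ex / np.where(ey == 0, np.inf, ey)
    crossings = (cond & (px < x_int)).sum(axis=1)
    return on_edge | (crossings % 2 == 1)


def rasterize_planar_contours(
    contours: Iterable[np.ndarray],
    target: ImageGeometry,
    organ: str = "",
    provenance: str = "",
) -> StructureMask:
    """Rasterize closed planar polygons (cm, patient coordinates) onto a grid.

    Each contour is an (k, 3) array whose points share one z value that must
    coincide with a grid slice center to within half a slice spacing.  A voxel
    is occupied iff its center is inside the polygon under the even–odd rule
    (edge points count as inside); several polygons on one slice are united,
    so a contour drawn inside another re-excludes (hole) only if it overlaps
    by even–odd within a *single* polygon ring — separate rings are unioned.
    """
    vox = np.zeros(target.shape, dtype=bool)
    zs = target.voxel_centers(2)
    xs = target.voxel_centers(0)
    ys = target.voxel_centers(1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    flat_x = gx.ravel()
    flat_y = gy.ravel()

    for ci, poly in enumerate(contours):
        poly = np.asarray(poly, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 3 or poly.shape[0] < 3:
            raise ValueError(f"contour {ci}: need an (k>=3, 3) point array")
        z = poly[:, 2]
        if np.ptp(z) > 1e-6:
            raise ValueError(f"contour {ci}: points are not coplanar in z")
        zc = float(z.mean())
        k = int(np.argmin(np.abs(zs - zc)))
        if abs(zs[k] - zc) > target.spacing[2] / 2 + 1e-9:
            raise GeometryError(
                f"contour {ci}: plane z={zc:.4f} cm matches no grid slice"
            )
        if _polygon_self_intersects(poly[:, :2]):
            warnings.warn(
                f"contour {ci}: self-intersecting polygon; even–odd fill applied",
                stacklevel=2,
            )
        inside = _points_in_polygon(flat_x, flat_y, poly[:, :2])
        vox[:, :, k] |= inside.reshape(len(xs), len(ys))
    return StructureMask(geometry=target, voxels=vox, organ=organ, provenance=provenance)


def _polygon_self_intersects(poly: np.ndarray) -> bool:
    """Brute-force proper-intersection test between non-adjacent edges."""
    n = len(poly)
    pts = np.vstack([poly, poly[:1]])
    for i in range(n):
        a, b = pts[i], pts[i + 1]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through closure
            c, d = pts[j], pts[j + 1]
            if _segments_properly_intersect(a, b, c, d):
                return True
    return False


def _segments_properly_intersect(a, b, c, d) -> bool:
    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    o1, o2 = orient(a, b, c), orient(a, b, d)
    o3, o4 = orient(c, d, a), orient(c, d, b)
    return (o1 * o2 < 0) and (o3 * o4 < 0)


def rasterize_rtstruct(
    rtstruct,
    roi_name: str,
    target: ImageGeometry,
    provenance: str = "",
) -> StructureMask:
    """Rasterize one ROI of a DICOM RT-Struct (pydicom Dataset or path).

    DICOM contour data are mm triplets; they are converted to cm before the
    planar rasterization.
    """
    import pydicom

    ds = rtstruct if hasattr(rtstruct, "StructureSetROISequence") else pydicom.dcmread(str(rtstruct))
    roi_number = None
    for roi in ds.StructureSetROISequence:
        if str(roi.ROIName) == roi_name:
            roi_number = roi.ROINumber
            break
    if roi_number is None:
        raise KeyError(f"ROI {roi_name!r} not found in RT-Struct")
    contours: list[np.ndarray] = []
    for rc in ds.ROIContourSequence:
        if rc.ReferencedROINumber != roi_number:
            continue
        for c in getattr(rc, "ContourSequence", []):
            pts_mm = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            contours.append(pts_mm / MM_PER_CM)
    return rasterize_planar_contours(contours, target, organ=roi_name, provenance=provenance)


def read_rtdose(rtdose) -> DoseGrid:
    """Read a DICOM RT-Dose grid (pydicom Dataset or path); applies DoseGridScaling.

    The pixel array is indexed (frame, row, col) = (z, y, x); it is transposed
    to the package's (x, y, z) order.
    """
    import pydicom

    ds = rtdose if hasattr(rtdose, "pixel_array") or hasattr(rtdose, "PixelData") else pydicom.dcmread(str(rtdose))
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    arr = ds.pixel_array.astype(float) * scaling  # (z, y, x)
    dose = np.ascontiguousarray(arr.transpose(2, 1, 0))
    dx, dy = (float(v) for v in ds.PixelSpacing[::-1])  # PixelSpacing is (row, col)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz_all = np.diff(offsets)
    if len(dz_all) and np.ptp(dz_all) > 1e-6:
        raise GeometryError("non-uniform GridFrameOffsetVector is not supported")
    dz = float(dz_all[0]) if len(dz_all) else 1.0
    origin_mm = np.asarray(ds.ImagePositionPatient, dtype=float)
    geom = ImageGeometry(
        shape=dose.shape,
        spacing=(dx / MM_PER_CM, dy / MM_PER_CM, abs(dz) / MM_PER_CM),
        origin=tuple(origin_mm / MM_PER_CM),
    )
    return DoseGrid(geometry=geom, dose=dose)


# ---------------------------------------------------------------------------
# Dose resampling
# ---------------------------------------------------------------------------

def resample_dose(dose: DoseGrid, target: ImageGeometry) -> tuple[DoseGrid, float]:
    """Trilinearly resample a dose grid onto ``target`` voxel centers.

    Returns the resampled grid and the out-of-field fraction: the fraction of
    target voxels whose centers lie outside the source extent (those voxels
    are set to 0 Gy).
    """
    from scipy.interpolate import RegularGridInterpolator

    src = dose.geometry
    axes = [src.voxel_centers(i) for i in range(3)]
    lo = [a[0] for a in axes]
    hi = [a[-1] for a in axes]
    tgt_axes = [target.voxel_centers(i) for i in range(3)]
    if any(tgt_axes[i][-1] < lo[i] or tgt_axes[i][0] > hi[i] for i in range(3)):
        raise GeometryError("target grid does not overlap the dose grid extent")

    # degenerate single-voxel axes: RegularGridInterpolator needs >= 2 points
    interp_axes = []
    dose_arr = dose.dose
    for i, a in enumerate(axes):
        if len(a) == 1:
            a = np.array([a[0] - src.spacing[i] / 2, a[0] + src.spacing[i] / 2])
            dose_arr = np.repeat(dose_arr, 2, axis=i)
        interp_axes.append(a)
    interp = RegularGridInterpolator(
        interp_axes, dose_arr, method="linear", bounds_error=False, fill_value=0.0
    )
    gx, gy, gz = np.meshgrid(*tgt_axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    values = interp(pts).reshape(target.shape)
    outside = np.zeros(target.shape, dtype=bool)
    for i in range(3):
        ax_out = (tgt_axes[i] < lo[i] - 1e-12) | (tgt_axes[i] > hi[i] + 1e-12)
        shape = [1, 1, 1]
        shape[i] = target.shape[i]
        outside |= ax_out.reshape(shape)
    values[outside] = 0.0
    frac_out = float(outside.mean())
    return DoseGrid(geometry=target, dose=np.clip(values, 0.0, None)), frac_out


# ---------------------------------------------------------------------------
# Structure-set manifests (cohort persistence)
# ---------------------------------------------------------------------------

def save_structure_set(sset: StructureSet, directory: str | Path) -> dict:
    """Write every mask of a case as NIfTI plus a JSON-able manifest entry."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entry: dict = {"case_id": sset.case_id, "masks": []}
    for m in sset.masks:
        fname = f"{sset.case_id}__{m.organ}__{m.provenance}.nii.gz"
        write_mask_volume(m, directory / fname)
        entry["masks"].append({"organ": m.organ, "provenance": m.provenance, "file": fname})
    return entry


def load_structure_set(entry: Mapping, directory: str | Path) -> StructureSet:
    directory = Path(directory)
    masks = [
        read_mask_volume(
            directory / rec["file"], organ=rec["organ"], provenance=rec["provenance"]
        )
        for rec in entry["masks"]
    ]
    return StructureSet(case_id=entry["case_id"], masks=masks)
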