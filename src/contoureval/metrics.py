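"""Geometric agreement metrics between a reference contour Vx and a test
contour Vy.

Overlap metrics (DSC, recall, precision) are voxel-count ratios.  Surface
distances (HD, HD95, MSD) are computed between boundary voxel centers, where
a boundary voxel is an occupied voxel with at least one unoccupied
6-neighbor (voxels on the grid edge count as boundary).  All distances are
in cm.

Conventions, chosen for reproducibility:

* HD is the symmetric Hausdorff distance: the max over both directed maxima.
* HD95 averages the two *directed* 95th percentiles (not their max), with
  linear interpolation between order statistics by default; a nearest-rank
  dialect is available via ``percentile_mode``.
* MSD averages the two directed mean nearest-point distances.
* Empty masks raise :class:`UndefinedMetricError` — silent zeros would
  corrupt cohort means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .volume_io import GeometryError, ImageGeometry, StructureMask


class UndefinedMetricError(ValueError):
    """A metric was requested for an empty mask or surface."""


@dataclass(frozen=True)
class SurfacePointSet:
    """Physical coordinates (cm) of a mask's boundary voxel centers."""

    points: np.ndarray  # (n, 3), cm
    source: str = ""

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.size == 0 or pts.shape[1] != 3:
            raise UndefinedMetricError("surface point set must be a nonempty (n,3) array")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class MetricRecord:
    """The six per-pair metrics plus provenance for reporting."""

    dsc: float
    recall: float
    precision: float
    hd: float
    hd95: float
    msd: float
    organ: str = ""
    case_id: str = ""
    method: str = ""

    FIELDS = ("dsc", "recall", "precision", "hd", "hd95", "msd")

    def as_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "organ": self.organ,
            "method": self.method,
            "dsc": self.dsc,
            "recall": self.recall,
            "precision": self.precision,
            "hd": self.hd,
            "hd95": self.hd95,
            "msd": self.msd,
        }


def _check_pair(vx: StructureMask, vy: StructureMask) -> None:
    if not vx.geometry.approx_equal(vy.geometry):
        raise GeometryError("reference and test masks are on different geometries")
    if vx.is_empty():
        raise UndefinedMetricError(
            f"reference mask is empty (organ={vx.organ!r}, provenance={vx.provenance!r})"
        )
    if vy.is_empty():
        raise UndefinedMetricError(
            f"test mask is empty (organ={vy.organ!r}, provenance={vy.provenance!r})"
        )


def overlap_metrics(vx: StructureMask, vy: StructureMask) -> tuple[float, float, float]:
    """DSC, recall and precision from voxel counts.

    DSC = 2|Vx∩Vy| / (|Vx|+|Vy|); recall = |∩|/|Vx| (reference coverage);
    precision = |∩|/|Vy| (test purity).  DSC is the harmonic mean of the two.
    """
    _check_pair(vx, vy)
    nx = vx.voxel_count
    ny = vy.voxel_count
    ni = int((vx.voxels & vy.voxels).sum())
    dsc = 2.0 * ni / (nx + ny)
    recall = ni / nx
    precision = ni / ny
    return dsc, recall, precision


def extract_surface(mask: StructureMask) -> SurfacePointSet:
    """Boundary voxel centers: occupied voxels with an unoccupied 6-neighbor.

    Out-of-grid counts as unoccupied, so voxels touching the grid edge are
    boundary.
    """
    if mask.is_empty():
        raise UndefinedMetricError(
            f"cannot extract surface of empty mask (organ={mask.organ!r})"
        )
    occ = mask.voxels
    padded = np.pad(occ, 1, mode="constant", constant_values=False)
    interior = np.ones_like(occ, dtype=bool)
    for axis in range(3):
        for shift in (-1, 1):
            interior &= np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
    boundary = occ & ~interior
    idx = np.argwhere(boundary)
    pts = mask.geometry.index_to_physical(idx)
    return SurfacePointSet(points=pts, source=f"{mask.organ}/{mask.provenance}")


def directed_distances(a: SurfacePointSet, b: SurfacePointSet) -> np.ndarray:
    """For each point of ``a``, the Euclidean distance to its nearest point
    of ``b`` (cm).  Uses a KD-tree; equals the all-pairs brute force."""
    tree = cKDTree(b.points)
    d, _ = tree.query(a.points, k=1)
    return np.asarray(d, dtype=float)


def hausdorff(a: SurfacePointSet, b: SurfacePointSet) -> float:
    """Symmetric Hausdorff distance (cm): max over both directed maxima."""
    return float(max(directed_distances(a, b).max(), directed_distances(b, a).max()))


def _p95(d: np.ndarray, mode: str) -> float:
    if mode == "interpolation":
        return float(np.percentile(d, 95))
    if mode == "nearest_rank":
        return float(np.percentile(d, 95, method="inverted_cdf"))
    raise ValueError(f"unknown percentile mode {mode!r}")


def hd95(
    a: SurfacePointSet, b: SurfacePointSet, percentile_mode: str = "interpolation"
) -> float:
    """Average of the two directed 95th-percentile distances (cm)."""
    fwd = _p95(directed_distances(a, b), percentile_mode)
    bwd = _p95(directed_distances(b, a), percentile_mode)
    return (fwd + bwd) / 2.0


def msd(a: SurfacePointSet, b: SurfacePointSet) -> float:
    """Mean surface distance (cm): average of the two directed means."""
    fwd = float(directed_distances(a, b).mean())
    bwd = float(directed_distances(b, a).mean())
    return (fwd + bwd) / 2.0


def evaluate_pair(
    vx: StructureMask,
    vy: StructureMask,
    case_id: str = "",
    percentile_mode: str = "interpolation",
) -> MetricRecord:
    """All six metrics for one (reference, test) pair.

    Errors from empty masks are re-raised with organ/case context.
    """
    try:
        dsc, recall, precision = overlap_metrics(vx, vy)
        sx = extract_surface(vx)
        sy = extract_surface(vy)
    except UndefinedMetricError as exc:
        raise UndefinedMetricError(
            f"case={case_id!r} organ={vx.organ or vy.organ!r}: {exc}"
        ) from exc
    d_xy = directed_distances(sx, sy)
    d_yx = directed_distances(sy, sx)
    hd_val = float(max(d_xy.max(), d_yx.max()))
    hd95_val = (_p95(d_xy, percentile_mode) + _p95(d_yx, percentile_mode)) / 2.0
    msd_val = (float(d_xy.mean()) + float(d_yx.mean())) / 2.0
    return MetricRecord(
        dsc=dsc,
        recall=recall,
        precision=precision,
        hd=hd_val,
        hd95=hd95_val,
        msd=msd_val,
        organ=vx.organ or vy.organ,
        case_id=case_id,
        method=vy.provenance,
    )
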