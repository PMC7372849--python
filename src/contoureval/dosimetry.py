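"""Dose–volume histograms, DVH endpoints and the relative dose difference.

The DVH is cumulative: the fraction of structure volume receiving at least
each dose level.  Voxels are counted fully in or out by their center (the
mask is binary); the curve is tabulated on uniform dose bins (default width
0.01 Gy).  Dx% endpoints (D98/D95/D50/D2) are read off the curve by linear
interpolation by default, with a nearest-bin dialect for cross-checking
against treatment-planning systems.

The dosimetric impact of contouring differences is the per-endpoint
relative difference against the manually segmented reference:
``delta = |(dose_ref - dose_auto) / dose_ref|``, reported in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .volume_io import DoseGrid, StructureMask, resample_dose

DEFAULT_ENDPOINTS = (98.0, 95.0, 50.0, 2.0)


class EmptyStructureError(ValueError):
    """DVH requested for an empty structure mask."""


class UndefinedRatioError(ValueError):
    """Relative dose difference requested against a zero reference dose."""


@dataclass
class DVHCurve:
    """Cumulative DVH: ``cum_volume_fraction[i]`` of the structure receives
    at least ``dose_bins[i]`` Gy."""

    dose_bins: np.ndarray
    cum_volume_fraction: np.ndarray
    total_volume_cm3: float

    def __post_init__(self) -> None:
        b = np.asarray(self.dose_bins, dtype=float)
        f = np.asarray(self.cum_volume_fraction, dtype=float)
        if b.ndim != 1 or b.shape != f.shape:
            raise ValueError("dose_bins and cum_volume_fraction must be equal-length 1D")
        if np.any(np.diff(b) <= 0):
            raise ValueError("dose_bins must be strictly increasing")
        if np.any(np.diff(f) > 1e-12) or f[0] != 1.0 or np.any((f < 0) | (f > 1)):
            raise ValueError("cumulative fractions must start at 1 and be nonincreasing in [0,1]")
        self.dose_bins = b
        self.cum_volume_fraction = f


@dataclass
class DoseMetrics:
    """DVH endpoints (Gy) and absolute volumes above thresholds (cm^3)."""

    d98: float
    d95: float
    d50: float
    d2: float
    v_at: dict[float, float] = field(default_factory=dict)
    organ: str = ""
    method: str = ""

    ENDPOINT_NAMES = ("d98", "d95", "d50", "d2")

    def endpoint(self, name: str) -> float:
        return getattr(self, name)


@dataclass
class DoseComparison:
    """Per-endpoint |relative dose difference| vs the manual reference, in %."""

    delta: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.delta.values()):
            raise ValueError("relative dose differences must be nonnegative")


def dvh(dose: DoseGrid, mask: StructureMask, bin_width: float = 0.01) -> DVHCurve:
    """Cumulative DVH of a structure on a dose grid.

    On geometry mismatch the dose is trilinearly resampled onto the mask's
    grid with a warning.
    """
    if mask.is_empty():
        raise EmptyStructureError(f"empty structure {mask.organ!r}: DVH undefined")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not dose.geometry.approx_equal(mask.geometry):
        warnings.warn(
            "dose and mask geometries differ; resampling dose onto the mask grid",
            stacklevel=2,
        )
        dose, _ = resample_dose(dose, mask.geometry)
    voxel_doses = dose.dose[mask.voxels]
    dmax = float(voxel_doses.max())
    n_bins = int(np.ceil(dmax / bin_width)) + 2
    bins = np.arange(n_bins) * bin_width
    # survival function: fraction of voxels with dose >= bin edge
    sorted_d = np.sort(voxel_doses)
    frac = 1.0 - np.searchsorted(sorted_d, bins, side="left") / len(sorted_d)
    frac[0] = 1.0  # dose >= 0 always holds
    return DVHCurve(
        dose_bins=bins,
        cum_volume_fraction=frac,
        total_volume_cm3=mask.volume_cm3,
    )


def dose_at_volume(curve: DVHCurve, x_percent: float, mode: str = "interpolation") -> float:
    """Dose (Gy) received by at least ``x_percent`` of the structure volume.

    ``mode="interpolation"`` interpolates linearly on the cumulative curve;
    ``mode="nearest"`` returns the highest tabulated bin dose still covering
    x% of the volume.
    """
    if not (0.0 < x_percent < 100.0):
        raise ValueError(f"x_percent must be in (0, 100), got {x_percent}")
    target = x_percent / 100.0
    f = curve.cum_volume_fraction
    b = curve.dose_bins
    if mode == "nearest":
        idx = np.nonzero(f >= target)[0]
        return float(b[idx[-1]]) if len(idx) else float(b[0])
    if mode != "interpolation":
        raise ValueError(f"unknown mode {mode!r}")
    # f is nonincreasing; np.interp needs increasing x
    return float(np.interp(target, f[::-1], b[::-1]))


def volume_at_dose(curve: DVHCurve, threshold: float, total_volume: float | None = None) -> float:
    """Absolute volume (cm^3) receiving at least ``threshold`` Gy."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    vol = curve.total_volume_cm3 if total_volume is None else total_volume
    if threshold <= curve.dose_bins[0]:
        return float(vol)
    if threshold > curve.dose_bins[-1]:
        return 0.0
    frac = float(np.interp(threshold, curve.dose_bins, curve.cum_volume_fraction))
    return frac * vol


def dose_metrics(
    dose: DoseGrid,
    mask: StructureMask,
    endpoints: tuple[float, ...] = DEFAULT_ENDPOINTS,
    v_thresholds: tuple[float, ...] = (),
    bin_width: float = 0.01,
    mode: str = "interpolation",
) -> DoseMetrics:
    """DVH endpoints Dx% (and optional VxGy volumes) for one structure."""
    curve = dvh(dose, mask, bin_width=bin_width)
    dx = {x: dose_at_volume(curve, x, mode=mode) for x in endpoints}
    v_at = {t: volume_at_dose(curve, t) for t in v_thresholds}
    return DoseMetrics(
        d98=dx.get(98.0, np.nan),
        d95=dx.get(95.0, np.nan),
        d50=dx.get(50.0, np.nan),
        d2=dx.get(2.0, np.nan),
        v_at=v_at,
        organ=mask.organ,
        method=mask.provenance,
    )


def delta_dose(ms: DoseMetrics, auto: DoseMetrics) -> DoseComparison:
    """|relative endpoint difference| of an auto-contour DVH against the
    manual-contour DVH, in percent."""
    delta: dict[str, float] = {}
    for name in DoseMetrics.ENDPOINT_NAMES:
        ref = ms.endpoint(name)
        test = auto.endpoint(name)
        if np.isnan(ref) or np.isnan(test):
            continue
        if ref <= 0:
            raise UndefinedRatioError(
                f"manual-contour endpoint {name} is {ref} Gy; relative difference undefined"
            )
        delta[name] = abs((ref - test) / ref) * 100.0
    return DoseComparison(delta=delta)


def boundary_gradient(dose: DoseGrid, mask: StructureMask) -> tuple[float, float]:
    """Max and mean dose-gradient magnitude (Gy/mm) over the structure surface.

    Central differences in the grid interior, one-sided at the grid edge
    (with a warning when surface voxels touch the edge).
    """
    from .metrics import extract_surface

    surf = extract_surface(mask)
    idx = np.rint(mask.geometry.physical_to_index(surf.points)).astype(int)
    shape = np.asarray(mask.geometry.shape)
    if ((idx == 0) | (idx == shape - 1)).any():
        warnings.warn(
            "structure touches the grid edge; one-sided differences used there",
            stacklevel=2,
        )
    grads = np.gradient(dose.dose, *[s for s in mask.geometry.spacing])  # Gy/cm
    gmag = np.sqrt(sum(g ** 2 for g in grads))
    vals = gmag[idx[:, 0], idx[:, 1], idx[:, 2]] / 10.0  # Gy/cm -> Gy/mm
    return float(vals.max()), float(vals.mean())
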