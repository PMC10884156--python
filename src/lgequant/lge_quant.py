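"""Semi-automated LGE quantification: remote-ROI statistics, n-SD and FWHM
thresholds, threshold application, planimetry, presence rule and the
percent-of-LV-mass conversion.

Protocol
--------
The thresholding reference is remote (visually normal) myocardium sampled
with circular ROIs on three consecutive short-axis slices, at least 100
pixels each; the per-slice means and SDs are combined as plain averages
("average mean SI and SD").  An n-SD threshold is ``mean + n x SD``; the
FWHM threshold is half of the maximal signal inside a hyperenhancement ROI.
A single threshold derived this way is applied to the whole myocardial
volume with a strict ``>`` comparator, with no connectivity filtering by
default.  Masses are converted to grams via :func:`lgequant.image_model.mass_of`
and reported as ``(M_LGE / M_M) x 100`` percent of LV mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .image_model import (
    GeometryError,
    LabelMap,
    LgeQuantError,
    SliceStack,
    mass_of,
)

__all__ = [
    "RoiError",
    "ProtocolError",
    "UndefinedPercentError",
    "DegenerateThresholdWarning",
    "RoiSpec",
    "RemoteStats",
    "ThresholdSpec",
    "QuantResult",
    "remote_stats",
    "nsd_threshold",
    "fwhm_threshold",
    "apply_threshold",
    "quantify",
    "lge_present",
]


class RoiError(LgeQuantError):
    """An ROI is empty, out of bounds, or resolves to too few pixels."""


class ProtocolError(LgeQuantError):
    """Input violates the measurement protocol (slice layout, view count)."""


class UndefinedPercentError(LgeQuantError):
    """Percent of LV mass is undefined because myocardial mass is zero."""


class DegenerateThresholdWarning(UserWarning):
    """Remote SD is zero, so all n-SD thresholds collapse onto the mean."""


@dataclass(frozen=True)
class RoiSpec:
    """A circular pixel ROI on one slice.

    ``center_rc`` is (row, col) in pixels; ``radius_px`` in pixels.  The ROI
    resolves to the set of in-bounds pixels within the circle; the protocol
    requires at least ``minimum_pixels`` of them after intersection with the
    myocardial mask.
    """

    slice_index: int
    center_rc: tuple[float, float]
    radius_px: float
    minimum_pixels: int = 100

    def pixel_mask(self, rows: int, cols: int) -> np.ndarray:
        rr, cc = np.ogrid[:rows, :cols]
        return (rr - self.center_rc[0]) ** 2 + (cc - self.center_rc[1]) ** 2 <= self.radius_px**2


@dataclass(frozen=True)
class RemoteStats:
    """Remote-myocardium reference statistics.

    ``mean_si`` is the arithmetic mean of the per-slice ROI means and ``sd``
    the arithmetic mean of the per-slice ROI SDs (population form), matching
    the averaged three-slice protocol.
    """

    per_slice_mean: tuple[float, ...]
    per_slice_sd: tuple[float, ...]
    mean_si: float
    sd: float
    n_slices_used: int


@dataclass(frozen=True)
class ThresholdSpec:
    """A named signal-intensity threshold (``visual`` carries no value)."""

    method: str
    threshold_value: float | None = None

    def __post_init__(self) -> None:
        if self.method != "visual":
            if self.threshold_value is None or not np.isfinite(self.threshold_value):
                raise LgeQuantError(f"{self.method}: threshold_value must be finite")
            if self.threshold_value < 0:
                raise LgeQuantError(f"{self.method}: threshold_value must be >= 0")


@dataclass
class QuantResult:
    """One method's LGE quantification for one subject read."""

    method: str
    lge_mass_g: float
    myo_mass_g: float
    lge_percent: float
    lge_mask: LabelMap
    threshold_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "threshold_value": self.threshold_value,
            "lge_mass_g": self.lge_mass_g,
            "myo_mass_g": self.myo_mass_g,
            "lge_percent": self.lge_percent,
            "lge_voxel_count": int(np.count_nonzero(self.lge_mask.labels)),
        }


# ---------------------------------------------------------------------------
# Remote-ROI statistics and thresholds
# ---------------------------------------------------------------------------

def remote_stats(
    stack: SliceStack,
    rois: Sequence[RoiSpec],
    myo_mask: LabelMap,
    *,
    require_consecutive: bool = True,
    sd_aggregation: str = "mean",
) -> RemoteStats:
    """Reference statistics from remote-myocardium ROIs.

    Each ROI is intersected with the myocardial mask and must retain at
    least its ``minimum_pixels``.  Per-slice SDs are population
    (n-denominator) SDs — immaterial at >= 100 pixels but pinned for
    bit-reproducibility.  ``sd_aggregation`` is ``"mean"`` (average of
    per-slice SDs, the default protocol) or ``"pooled"`` (population SD of
    all ROI pixels combined).
    """
    if not myo_mask.same_geometry_as(stack):
        raise GeometryError("myocardial mask geometry does not match the stack")
    if len(rois) < 1:
        raise RoiError("at least one remote ROI is required")
    slices = [roi.slice_index for roi in rois]
    if require_consecutive and sorted(slices) != list(range(min(slices), min(slices) + len(slices))):
        raise ProtocolError(
            f"remote ROIs must lie on consecutive slices (got {slices}); "
            "pass require_consecutive=False to override"
        )

    n_slices, rows, cols = stack.shape
    means, sds, pooled_pixels = [], [], []
    for roi in rois:
        if not 0 <= roi.slice_index < n_slices:
            raise RoiError(f"ROI slice {roi.slice_index} outside [0, {n_slices})")
        sel = roi.pixel_mask(rows, cols) & myo_mask.as_bool()[roi.slice_index]
        count = int(np.count_nonzero(sel))
        if count < roi.minimum_pixels:
            raise RoiError(
                f"ROI on slice {roi.slice_index} resolves to {count} myocardial pixels; "
                f"protocol requires >= {roi.minimum_pixels}"
            )
        vals = stack.intensities[roi.slice_index][sel]
        means.append(float(vals.mean()))
        sds.append(float(vals.std(ddof=0)))
        pooled_pixels.append(vals)

    if sd_aggregation == "mean":
        sd = float(np.mean(sds))
    elif sd_aggregation == "pooled":
        sd = float(np.concatenate(pooled_pixels).std(ddof=0))
    else:
        raise LgeQuantError(f"unknown sd_aggregation {sd_aggregation!r}")
    return RemoteStats(
        per_slice_mean=tuple(means),
        per_slice_sd=tuple(sds),
        mean_si=float(np.mean(means)),
        sd=sd,
        n_slices_used=len(rois),
    )


def nsd_threshold(stats: RemoteStats, n: float) -> ThresholdSpec:
    """Threshold at ``n`` SDs above the remote mean signal intensity."""
    if n <= 0:
        raise LgeQuantError(f"n must be > 0, got {n}")
    if stats.sd == 0:
        warnings.warn(
            "remote SD is 0: the n-SD threshold degenerates to the remote mean",
            DegenerateThresholdWarning,
            stacklevel=2,
        )
    name = f"sd{n:g}" if float(n).is_integer() else f"sd{n}"
    return ThresholdSpec(method=name, threshold_value=stats.mean_si + n * stats.sd)


def fwhm_threshold(
    stack: SliceStack,
    hyper_roi: RoiSpec,
    myo_mask: LabelMap | None = None,
    *,
    max_percentile: float | None = None,
) -> ThresholdSpec:
    """Full-width-at-half-maximum threshold: 50% of the maximal signal in a
    hyperenhancement ROI.

    ``max_percentile`` replaces the plain maximum with an upper percentile
    (e.g. 99) to tame hot pixels; default is the plain maximum.
    """
    n_slices, rows, cols = stack.shape
    if not 0 <= hyper_roi.slice_index < n_slices:
        raise RoiError(f"hyper ROI slice {hyper_roi.slice_index} outside [0, {n_slices})")
    sel = hyper_roi.pixel_mask(rows, cols)
    if myo_mask is not None:
        if not myo_mask.same_geometry_as(stack):
            raise GeometryError("myocardial mask geometry does not match the stack")
        sel = sel & myo_mask.as_bool()[hyper_roi.slice_index]
    if not sel.any():
        raise RoiError("hyper ROI resolves to zero pixels")
    vals = stack.intensities[hyper_roi.slice_index][sel]
    peak = float(vals.max()) if max_percentile is None else float(np.percentile(vals, max_percentile))
    return ThresholdSpec(method="fwhm", threshold_value=0.5 * peak)


# ---------------------------------------------------------------------------
# Threshold application and quantification
# ---------------------------------------------------------------------------

def apply_threshold(stack: SliceStack, myo_mask: LabelMap, thr: ThresholdSpec) -> LabelMap:
    """Classify as LGE every myocardial voxel strictly above the threshold.

    The strict ``>`` comparator means a zero-SD (noiseless) reference does
    not classify the entire wall as enhanced.  No connectivity filtering is
    applied.
    """
    if thr.threshold_value is None:
        raise LgeQuantError(f"method {thr.method!r} carries no threshold value")
    if not myo_mask.same_geometry_as(stack):
        raise GeometryError("myocardial mask geometry does not match the stack")
    mask = myo_mask.as_bool() & (stack.intensities > thr.threshold_value)
    return LabelMap(mask, stack.pixel_spacing_mm, stack.slice_thickness_mm, stack.slice_gap_mm)


def quantify(
    stack: SliceStack,
    myo_mask: LabelMap,
    thr: ThresholdSpec | None = None,
    planimetry_mask: LabelMap | None = None,
    *,
    min_cluster_voxels: int = 0,
) -> QuantResult:
    """LGE mass, myocardial mass and percent of LV mass for one method.

    Either a threshold (semi-automated arms) or a planimetry mask (visual
    arm) must be supplied.  The planimetry mask is clipped to the myocardium.
    ``min_cluster_voxels`` optionally removes connected components smaller
    than the given size (off by default; the standard protocol uses none).
    """
    if (thr is None) == (planimetry_mask is None):
        raise LgeQuantError("supply exactly one of a threshold or a planimetry mask")
    myo_mass = mass_of(myo_mask)
    if myo_mass.mass_g <= 0:
        raise UndefinedPercentError("myocardial mass is zero; LGE percent undefined")

    if thr is not None:
        lge_mask = apply_threshold(stack, myo_mask, thr)
        method = thr.method
        thr_value = thr.threshold_value
    else:
        if not planimetry_mask.same_geometry_as(myo_mask):
            raise GeometryError("planimetry mask geometry does not match the myocardial mask")
        lge_mask = LabelMap(
            planimetry_mask.as_bool() & myo_mask.as_bool(),
            myo_mask.pixel_spacing_mm,
            myo_mask.slice_thickness_mm,
            myo_mask.slice_gap_mm,
        )
        method = "visual"
        thr_value = None

    if min_cluster_voxels > 1:
        from scipy import ndimage

        lab, n = ndimage.label(lge_mask.labels)
        if n:
            sizes = np.bincount(lab.ravel())
            keep = sizes >= min_cluster_voxels
            keep[0] = False
            lge_mask = LabelMap(
                keep[lab],
                lge_mask.pixel_spacing_mm,
                lge_mask.slice_thickness_mm,
                lge_mask.slice_gap_mm,
            )

    lge_mass = mass_of(lge_mask)
    return QuantResult(
        method=method,
        lge_mass_g=lge_mass.mass_g,
        myo_mass_g=myo_mass.mass_g,
        lge_percent=100.0 * lge_mass.mass_g / myo_mass.mass_g,
        lge_mask=lge_mask,
        threshold_value=thr_value,
    )


def lge_present(per_view_flags: Mapping[str, bool]) -> bool:
    """Presence rule: LGE is present only if visible in at least two
    orthogonal views (guards against false-positive single-view findings)."""
    if len(per_view_flags) < 2:
        raise ProtocolError(
            f"presence assessment requires >= 2 views, got {len(per_view_flags)}"
        )
    return sum(bool(v) for v in per_view_flags.values()) >= 2
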