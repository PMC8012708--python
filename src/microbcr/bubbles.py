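"""Bubble detection, ellipse fitting, and equivalent spherical diameter.

Static imaging of a sparged column yields dark bubbles on a bright
background.  Each connected dark component is fitted as an ellipse from its
second-order image moments; treating the bubble as an oblate ellipsoid of
revolution about its minor axis, the diameter of the equal-volume sphere is

    d_SB = ∛(8 · (d_major/2)² · (d_minor/2)) = ∛(d_major² · d_minor).

Touching or merged bubbles are not split; an optional solidity filter can
drop merged components instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, segmentation
from skimage.filters import threshold_otsu

from microbcr.errors import InsufficientDataError
from microbcr.frames import FrameSequence

__all__ = [
    "BubbleMeasurement",
    "PopulationStats",
    "segment_bubbles",
    "fit_ellipse_axes",
    "equivalent_sphere_diameter",
    "bubble_population_stats",
    "measure_bubbles",
]


@dataclass(frozen=True)
class BubbleMeasurement:
    """One detected bubble in one frame (lengths in mm, positions in px)."""

    frame_index: int
    center: tuple[float, float]  # (row, col), pixels, ROI-global coordinates
    d_major_mm: float
    d_minor_mm: float
    d_sb_mm: float
    area_px: int

    def __post_init__(self) -> None:
        if not (self.d_major_mm >= self.d_minor_mm > 0):
            raise ValueError("require d_major >= d_minor > 0")


@dataclass(frozen=True)
class PopulationStats:
    """Summary of a bubble population's equivalent diameters (mm)."""

    n: int
    mean_mm: float
    sd_mm: float
    max_mm: float


def equivalent_sphere_diameter(d_major_mm: float, d_minor_mm: float) -> float:
    """Equal-volume sphere diameter of a rotation ellipsoid (mm).

    d_SB = ∛(d_major² · d_minor); reduces to the identity for a sphere.
    """
    if d_major_mm <= 0 or d_minor_mm <= 0:
        raise ValueError("axes must be > 0")
    return float(np.cbrt(d_major_mm**2 * d_minor_mm))


def segment_bubbles(
    seq: FrameSequence,
    min_area_px: int = 20,
    threshold: str | float = "otsu",
    solidity_min: float | None = None,
) -> list[list[measure._regionprops.RegionProperties]]:
    """Label dark components in each frame's ROI.

    Pixels below the threshold (Otsu on the ROI histogram, or a fixed grey
    value) form candidate bubbles.  Components smaller than ``min_area_px``
    or touching the ROI border are discarded; ``solidity_min`` optionally
    drops non-convex (merged) components.  Deterministic: no randomness is
    involved anywhere.

    Returns one list of ``skimage`` region objects per frame (empty lists
    for frames without bubbles); region coordinates are relative to the ROI.
    """
    out: list[list] = []
    for i in range(len(seq)):
        roi = seq.roi_view(i)
        if threshold == "otsu":
            # degenerate (constant) ROI has no threshold — report no bubbles
            if roi.min() == roi.max():
                out.append([])
                continue
            thr = threshold_otsu(roi)
        else:
            thr = float(threshold)
        mask = roi < thr
        mask = segmentation.clear_border(mask)
        labels = measure.label(mask, connectivity=2)
        regions = [r for r in measure.regionprops(labels) if r.area >= min_area_px]
        if solidity_min is not None:
            regions = [r for r in regions if r.solidity >= solidity_min]
        out.append(regions)
    return out


def fit_ellipse_axes(
    region, pixel_scale_mm: float
) -> tuple[float, float, float]:
    """Axes (mm) and orientation (rad) of the moment-equivalent ellipse.

    Uses the component's normalized second central moments; the returned
    lengths satisfy ``d_major >= d_minor`` regardless of orientation.
    """
    if region.area < 5:
        raise InsufficientDataError("component below 5 px cannot be fitted")
    d_major = region.axis_major_length * pixel_scale_mm
    d_minor = region.axis_minor_length * pixel_scale_mm
    if d_minor <= 0:
        raise InsufficientDataError("degenerate (collinear) component")
    return d_major, d_minor, float(region.orientation)


def measure_bubbles(
    seq: FrameSequence,
    min_area_px: int = 20,
    threshold: str | float = "otsu",
    solidity_min: float | None = None,
) -> list[BubbleMeasurement]:
    """Segment every frame and fit each component; the full sizing chain."""
    r0, _, c0, _ = seq.roi
    out = []
    for idx, regions in enumerate(
        segment_bubbles(seq, min_area_px, threshold, solidity_min)
    ):
        for region in regions:
            dmaj, dmin, _ = fit_ellipse_axes(region, seq.pixel_scale_mm)
            cy, cx = region.centroid
            out.append(
                BubbleMeasurement(
                    frame_index=idx,
                    center=(cy + r0, cx + c0),
                    d_major_mm=dmaj,
                    d_minor_mm=dmin,
                    d_sb_mm=equivalent_sphere_diameter(dmaj, dmin),
                    area_px=int(region.area),
                )
            )
    return out


def bubble_population_stats(
    measurements: list[BubbleMeasurement], max_n: int = 400
) -> PopulationStats:
    """Mean ± sd and maximum of d_SB over at most ``max_n`` measurements.

    Measurements are taken in chronological order (first ``max_n``); the sd
    is the population standard deviation (ddof=0).  An empty input yields an
    all-NaN summary with n = 0.
    """
    used = measurements[:max_n]
    if not used:
        return PopulationStats(n=0, mean_mm=float("nan"), sd_mm=float("nan"),
                               max_mm=float("nan"))
    d = np.array([m.d_sb_mm for m in used])
    return PopulationStats(
        n=len(d), mean_mm=float(d.mean()), sd_mm=float(d.std()), max_mm=float(d.max())
    )
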