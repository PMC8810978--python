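"""Planar-image H/CL quantification.

The heart/contralateral ratio (H/CL) is computed from a planar
scintigraphic count image by summing the counts inside a circular heart
ROI and inside the same circle mirrored across the sternal midline, then
dividing the two totals.  Pixel membership uses the pixel-center rule:
a pixel belongs to the ROI when its center lies within ``radius`` of the
ROI center, boundary inclusive.  Coordinates are 0-based ``(row, col)``.

Restricting the midline to integer or half-integer columns guarantees the
mirrored ROI contains exactly the same number of pixels as the heart ROI,
so the ratio compares equal-area regions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlanarImage",
    "CircularROI",
    "HClResult",
    "GeometryError",
    "QuantError",
    "mirror_roi",
    "roi_pixels",
    "sum_counts",
    "compute_hcl",
    "centroid_roi",
]

PROJECTIONS = ("anterior", "posterior", "oblique")


class QuantError(ValueError):
    """Invalid quantification input (domain error)."""


class GeometryError(QuantError):
    """ROI geometry incompatible with the image."""


@dataclass
class PlanarImage:
    """A 2-D grid of detected gamma events.

    Parameters
    ----------
    counts
        Nonnegative integer counts per pixel, shape (rows, cols).
    pixel_spacing
        Pixel size in mm.
    time_post_injection
        Acquisition time after tracer administration, hours.
    projection
        One of ``anterior``, ``posterior``, ``oblique``.
    """

    counts: np.ndarray
    pixel_spacing: float = 4.42
    time_post_injection: float = 3.0
    projection: str = "anterior"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise QuantError("counts must be a 2-D array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise QuantError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise QuantError("counts must be nonnegative")
        if self.pixel_spacing <= 0:
            raise QuantError("pixel_spacing must be positive")
        if self.projection not in PROJECTIONS:
            raise QuantError(f"projection must be one of {PROJECTIONS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class CircularROI:
    """Circle in continuous pixel coordinates: center (row, col), radius."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise QuantError("ROI radius must be positive")


@dataclass(frozen=True)
class HClResult:
    """H/CL quantification outcome for one image."""

    heart_counts: int
    contralateral_counts: int
    ratio: float
    n_pixels: int
    heart_roi: CircularROI = field(repr=False, default=None)  # type: ignore[assignment]
    contralateral_roi: CircularROI = field(repr=False, default=None)  # type: ignore[assignment]


def mirror_roi(roi: CircularROI, midline_col: float) -> CircularROI:
    """Reflect an ROI across a vertical midline: col -> 2*midline_col - col."""
    row, col = roi.center
    return CircularROI((row, 2.0 * midline_col - col), roi.radius)


def roi_pixels(roi: CircularROI) -> tuple[np.ndarray, np.ndarray]:
    """Integer pixel centers inside the ROI (may extend beyond any image).

    Returns (rows, cols) index arrays in a fixed raster order.
    """
    cr, cc = roi.center
    r = roi.radius
    rows = np.arange(math.ceil(cr - r), math.floor(cr + r) + 1)
    cols = np.arange(math.ceil(cc - r), math.floor(cc + r) + 1)
    rr, cc_grid = np.meshgrid(rows, cols, indexing="ij")
    inside = (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= r**2 + 1e-9
    return rr[inside], cc_grid[inside]


def sum_counts(image: PlanarImage, roi: CircularROI) -> tuple[int, int]:
    """Total counts and pixel count inside an ROI.

    Raises
    ------
    GeometryError
        If any member pixel center lies outside the image.
    """
    rows, cols = roi_pixels(roi)
    h, w = image.shape
    if rows.size == 0:
        return 0, 0
    if rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w:
        raise GeometryError(
            f"ROI centered at {roi.center} with radius {roi.radius} "
            f"extends beyond the {h}x{w} image"
        )
    total = int(image.counts[rows, cols].sum())
    return total, int(rows.size)


def _check_midline(midline_col: float) -> None:
    if abs(2.0 * midline_col - round(2.0 * midline_col)) > 1e-9:
        raise GeometryError(
            "midline_col must be an integer or half-integer column so that "
            "the mirrored ROI covers the same number of pixels"
        )


def compute_hcl(
    image: PlanarImage, heart_roi: CircularROI, midline_col: float
) -> HClResult:
    """Heart/contralateral count ratio from a heart ROI and a midline.

    The contralateral ROI is the heart ROI mirrored across ``midline_col``;
    both use the same pixel-center membership rule and contain the same
    number of pixels.

    Raises
    ------
    GeometryError
        If either ROI extends beyond the image or the midline is not on an
        integer/half-integer column.
    QuantError
        If the contralateral total is zero (ratio undefined).
    """
    _check_midline(midline_col)
    if image.projection != "anterior" or abs(image.time_post_injection - 3.0) > 0.25:
        warnings.warn(
            "H/CL reference values assume the anterior projection acquired "
            f"3 h post-injection; got {image.projection} at "
            f"{image.time_post_injection} h",
            stacklevel=2,
        )
    cl_roi = mirror_roi(heart_roi, midline_col)
    heart_total, n_heart = sum_counts(image, heart_roi)
    cl_total, n_cl = sum_counts(image, cl_roi)
    if n_heart != n_cl:  # pragma: no cover - excluded by the midline check
        raise GeometryError("heart and contralateral ROIs differ in pixel count")
    if cl_total == 0:
        raise QuantError("contralateral total is zero; H/CL undefined")
    return HClResult(
        heart_counts=heart_total,
        contralateral_counts=cl_total,
        ratio=heart_total / cl_total,
        n_pixels=n_heart,
        heart_roi=heart_roi,
        contralateral_roi=cl_roi,
    )


def centroid_roi(
    image: PlanarImage,
    search_box: tuple[int, int, int, int],
    radius: float,
) -> CircularROI:
    """Circular ROI centered on the count-weighted centroid of a search box.

    ``search_box`` is (row_start, row_stop, col_start, col_stop), half-open,
    in pixel indices.  Convenience for reproducible heart-ROI placement when
    no manual center is supplied.
    """
    r0, r1, c0, c1 = search_box
    sub = image.counts[r0:r1, c0:c1].astype(float)
    total = sub.sum()
    if total <= 0:
        raise QuantError("search box contains no counts; centroid undefined")
    rows = np.arange(r0, r1, dtype=float)
    cols = np.arange(c0, c1, dtype=float)
    crow = float((sub.sum(axis=1) * rows).sum() / total)
    ccol = float((sub.sum(axis=0) * cols).sum() / total)
    return CircularROI((crow, ccol), radius)
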