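"""Mask-based shape descriptors on sub-pixel contours.

Five descriptors characterise a region's outline after normalizing it to a
common major-axis length of 1.0 (so they capture shape, not size):

- circularity  = 4*pi*Area / Perimeter^2      (1 for a perfect circle)
- eccentricity = sqrt(a^2 - b^2) / a          (foci distance / major axis)
- solidity     = Area / convex-hull area      (1 iff convex)
- extent       = Area / object-aligned bounding-box area
- minor_axis_length = b / a                   (best-fit-ellipse width)

where a, b are the semi-axes of the ellipse sharing the region's second
central moments.  All quantities are exact polygon integrals over the
sub-pixel contour, not pixel counts: pixel-count perimeters systematically
bias circularity below 1 even for discs, which would break the descriptor's
calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from skimage import measure

from .outline import Outline, GeometryError, ellipse_axes_from_moments
from .records import SpecimenRecord


class SegmentationError(ValueError):
    """Mask does not contain exactly one usable foreground component."""


@dataclass(frozen=True)
class EllipseFit:
    """Moment-based best-fit ellipse (semi-axes a >= b > 0)."""

    center: tuple[float, float]
    major_semi_axis: float
    minor_semi_axis: float
    orientation: float


@dataclass(frozen=True)
class ShapeMetrics:
    circularity: float
    eccentricity: float
    solidity: float
    extent: float
    minor_axis_length: float
    raw_area: float
    raw_perimeter: float


MIN_COMPONENT_PIXELS = 9


#: components at least this large get Gaussian pre-smoothing (sigma 0.8 px),
#: which removes the marching-squares staircase bias from the perimeter
SMOOTHING_MIN_PIXELS = 100
SMOOTHING_SIGMA = 0.8


def extract_contour(mask: np.ndarray) -> Outline:
    """Sub-pixel boundary of the single foreground component of a binary mask.

    Iso-contour at level 0.5 with linear interpolation (marching squares);
    the largest closed contour is returned with CCW orientation enforced.
    Components of at least ``SMOOTHING_MIN_PIXELS`` are lightly smoothed
    (Gaussian, ``SMOOTHING_SIGMA`` px) before contouring: on a hard binary
    mask the
    0.5-level contour follows pixel staircases and overestimates perimeters
    by ~5%, which would destroy the circularity calibration.
    """
    from scipy.ndimage import gaussian_filter

    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise SegmentationError("empty mask")
    labels, n = measure.label(mask, return_num=True)
    sizes = np.bincount(labels.ravel())[1:]
    large = np.flatnonzero(sizes >= MIN_COMPONENT_PIXELS)
    if len(large) == 0:
        raise SegmentationError(
            f"no component with >= {MIN_COMPONENT_PIXELS} px; sizes: {sorted(sizes)}"
        )
    if len(large) > 1:
        raise SegmentationError(
            f"multiple large components; sizes: {sorted(sizes[large].tolist())}"
        )
    keep = labels == (large[0] + 1)
    padded = np.pad(keep.astype(float), 2)
    if sizes[large[0]] >= SMOOTHING_MIN_PIXELS:
        smoothed = gaussian_filter(padded, SMOOTHING_SIGMA)
        if smoothed.max() > 0.5:
            padded = smoothed
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise SegmentationError("no iso-contour found")
    contour = max(contours, key=len)
    # find_contours gives (row, col) with a closing duplicate point; convert
    # to (x=col, y=row) continuous coordinates and drop the duplicate
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    pts = np.column_stack([contour[:, 1], contour[:, 0]]) - 2.0  # unpad
    return Outline(pts).ensure_ccw()


def fit_ellipse(outline: Outline) -> EllipseFit:
    mu_xx, mu_yy, mu_xy = outline.second_central_moments()
    major, minor, theta = ellipse_axes_from_moments(mu_xx, mu_yy, mu_xy)
    if minor <= 0:
        raise GeometryError("degenerate outline: zero minor axis")
    cx, cy = outline.centroid()
    return EllipseFit((float(cx), float(cy)), major / 2.0, minor / 2.0, theta)


def normalize_outline(outline: Outline) -> Outline:
    """Centroid at origin, major axis vertical, major-axis length exactly 1.0.

    Uniform scaling preserves aspect ratio; the operation is idempotent up to
    the 180-degree rotational ambiguity of an axis.
    """
    if outline.area() <= 0:
        raise GeometryError("zero-area outline cannot be normalized")
    fit = fit_ellipse(outline)
    c = outline.centroid()
    pts = outline.points - c
    # rotate the major-axis direction onto +y
    angle = math.pi / 2.0 - fit.orientation
    # choose the representative closest to identity so the map is idempotent
    angle = (angle + math.pi) % math.pi
    if angle > math.pi / 2.0:
        angle -= math.pi
    ca, sa = math.cos(angle), math.sin(angle)
    pts = pts @ np.array([[ca, sa], [-sa, ca]])
    out = Outline(pts / (2.0 * fit.major_semi_axis)).ensure_ccw()
    return out


def compute_shape_metrics(outline: Outline,
                          raw_outline: Outline | None = None) -> ShapeMetrics:
    """Five descriptors of a normalized outline (plus raw area/perimeter).

    ``raw_outline``, when given, supplies ``raw_area``/``raw_perimeter`` in
    the original (pixel) units; otherwise they are taken from ``outline``.
    """
    if not outline.is_simple():
        raise GeometryError("self-intersecting outline")
    area = outline.area()
    perim = outline.perimeter()
    if area <= 0 or perim <= 0:
        raise GeometryError("degenerate outline")
    circularity = 4.0 * math.pi * area / perim**2
    mu_xx, mu_yy, mu_xy = outline.second_central_moments()
    major, minor, _ = ellipse_axes_from_moments(mu_xx, mu_yy, mu_xy)
    ecc = math.sqrt(max(major**2 - minor**2, 0.0)) / major
    hull = ConvexHull(outline.points)
    # hull area via the same shoelace arithmetic as the region area, so a
    # convex outline yields solidity exactly 1
    hv = outline.points[hull.vertices]
    hull_area = 0.5 * abs(float(np.sum(
        hv[:, 0] * np.roll(hv[:, 1], -1) - np.roll(hv[:, 0], -1) * hv[:, 1])))
    solidity = area / hull_area
    if solidity > 1.0 - 1e-9:
        solidity = 1.0
    w = outline.points[:, 0].max() - outline.points[:, 0].min()
    h = outline.points[:, 1].max() - outline.points[:, 1].min()
    extent = area / (w * h)
    raw = raw_outline if raw_outline is not None else outline
    return ShapeMetrics(
        circularity=float(min(circularity, 1.0 + 1e-12)),
        eccentricity=float(ecc),
        solidity=float(min(solidity, 1.0)),
        extent=float(extent),
        minor_axis_length=float(minor / major),
        raw_area=float(raw.area()),
        raw_perimeter=float(raw.perimeter()),
    )


def metrics_from_mask(mask: np.ndarray) -> ShapeMetrics:
    """Full pipeline for one mask: contour -> normalize -> descriptors."""
    raw = extract_contour(mask)
    return compute_shape_metrics(normalize_outline(raw), raw_outline=raw)


METRIC_COLUMNS = ["circularity", "eccentricity", "solidity", "extent",
                  "minor_axis_length"]


def compute_metrics_table(records: list[SpecimenRecord], root: str | Path,
                          region: str = "keyhole") -> pd.DataFrame:
    """Descriptor table for every specimen's shell or keyhole mask."""
    from PIL import Image

    if region not in ("shell", "keyhole"):
        raise ValueError("region must be 'shell' or 'keyhole'")
    root = Path(root)
    rows = []
    for rec in records:
        path = rec.mask_path if region == "shell" else rec.keyhole_mask_path
        if path is None:
            continue
        mask = np.asarray(Image.open(root / path)) > 127
        m = metrics_from_mask(mask)
        rows.append({
            "specimen_id": rec.specimen_id,
            "species": rec.species,
            "clade": rec.clade,
            "location": rec.location,
            "region": region,
            "circularity": m.circularity,
            "eccentricity": m.eccentricity,
            "solidity": m.solidity,
            "extent": m.extent,
            "minor_axis_length": m.minor_axis_length,
            "raw_area": m.raw_area,
            "raw_perimeter": m.raw_perimeter,
        })
    return pd.DataFrame(rows)
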