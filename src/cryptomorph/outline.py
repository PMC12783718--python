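"""Closed polygonal outlines in continuous 2-D coordinates.

An :class:`Outline` is an ordered list of ``(x, y)`` vertices describing a
simple closed polygon; the first point is not repeated.  The package-wide
orientation convention is counter-clockwise, i.e. positive shoelace signed
area.  All region quantities (area, centroid, second central moments) are
exact polygon integrals, so shape descriptors computed from them are free of
pixel-counting bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon


class GeometryError(ValueError):
    """Raised for degenerate or invalid outline geometry."""


@dataclass(frozen=True)
class Outline:
    """Simple closed polyline, counter-clockwise, first point not repeated."""

    points: np.ndarray = field()

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise GeometryError(
                f"outline needs an (n>=3, 2) point array, got shape {pts.shape}"
            )
        object.__setattr__(self, "points", pts)

    # -- basic quantities ---------------------------------------------------

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        return 0.5 * float(np.sum(x * yn - xn * y))

    def area(self) -> float:
        return abs(self.signed_area())

    def perimeter(self) -> float:
        d = np.roll(self.points, -1, axis=0) - self.points
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    def centroid(self) -> np.ndarray:
        """Area centroid of the enclosed region (exact polygon formula)."""
        x, y = self.points[:, 0], self.points[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = 0.5 * np.sum(cross)
        if abs(a) < 1e-300:
            raise GeometryError("zero-area outline has no centroid")
        cx = np.sum((x + xn) * cross) / (6.0 * a)
        cy = np.sum((y + yn) * cross) / (6.0 * a)
        return np.array([cx, cy])

    def second_central_moments(self) -> tuple[float, float, float]:
        """Normalized second central moments (mu_xx, mu_yy, mu_xy) / area.

        Exact Green's-theorem polygon integrals of x^2, y^2 and xy over the
        enclosed region, about the area centroid, divided by the area.  For an
        ellipse with semi-axes a >= b these equal (a^2/4, b^2/4, 0) in the
        axis-aligned frame.
        """
        c = self.centroid()
        x = self.points[:, 0] - c[0]
        y = self.points[:, 1] - c[1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = 0.5 * np.sum(cross)
        ixx = np.sum(cross * (x * x + x * xn + xn * xn)) / 12.0
        iyy = np.sum(cross * (y * y + y * yn + yn * yn)) / 12.0
        ixy = np.sum(cross * (x * yn + 2 * x * y + 2 * xn * yn + xn * y)) / 24.0
        return float(ixx / a), float(iyy / a), float(ixy / a)

    def is_simple(self) -> bool:
        return Polygon(self.points).is_valid

    def is_ccw(self) -> bool:
        return self.signed_area() > 0

    # -- constructive helpers ----------------------------------------------

    def ensure_ccw(self) -> "Outline":
        if self.is_ccw():
            return self
        return Outline(self.points[::-1].copy())

    def translated(self, dx: float, dy: float) -> "Outline":
        return Outline(self.points + np.array([dx, dy]))

    def scaled(self, factor: float) -> "Outline":
        if factor <= 0:
            raise GeometryError("scale factor must be positive")
        return Outline(self.points * factor)

    def rotated(self, angle: float) -> "Outline":
        """Rotate about the origin by ``angle`` radians (CCW positive)."""
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        return Outline(self.points @ rot.T)

    def validate(self) -> "Outline":
        """Assert the package invariants: simple, CCW, >= 3 points."""
        if not self.is_ccw():
            raise GeometryError("outline is not counter-clockwise (signed area <= 0)")
        if not self.is_simple():
            raise GeometryError("outline is self-intersecting")
        return self


def ellipse_axes_from_moments(
    mu_xx: float, mu_yy: float, mu_xy: float
) -> tuple[float, float, float]:
    """Best-fit-ellipse (major_len, minor_len, orientation) from moments.

    The ellipse with the same normalized second central moments as the region
    has axis lengths ``4*sqrt(lambda)`` for the two eigenvalues of the moment
    matrix.  Orientation is the angle of the major-axis eigenvector, in
    radians, measured from the +x axis.
    """
    m = np.array([[mu_xx, mu_xy], [mu_xy, mu_yy]])
    vals, vecs = np.linalg.eigh(m)  # ascending
    vals = np.clip(vals, 0.0, None)
    major = 4.0 * np.sqrt(vals[1])
    minor = 4.0 * np.sqrt(vals[0])
    v = vecs[:, 1]
    theta = float(np.arctan2(v[1], v[0]))
    return float(major), float(minor), theta
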