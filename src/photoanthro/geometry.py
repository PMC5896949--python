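"""Planar Euclidean primitives used throughout the measurement pipeline.

Image coordinates follow raster convention: origin at the top-left pixel
corner, ``x`` increasing rightwards and ``y`` increasing downwards, in
float pixels (sub-pixel annotations are allowed, and landmarks may fall
outside the frame).  World coordinates live in the participant /
checkerboard plane, in millimetres, with ``z = 0`` by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ImagePoint",
    "WorldPoint",
    "Line2D",
    "line_through",
    "project_point_to_line",
    "euclidean",
]

_DEGENERATE_SEP = 1e-9


class GeometryError(ValueError):
    """Raised for degenerate geometric configurations."""


@dataclass(frozen=True)
class ImagePoint:
    """A 2-D point in pixel coordinates (x rightwards, y downwards)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite image point ({self.x}, {self.y})")


@dataclass(frozen=True)
class WorldPoint:
    """A 2-D point in the participant plane, in millimetres."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite world point ({self.x}, {self.y})")


@dataclass(frozen=True)
class Line2D:
    """A line ``a*x + b*y + c = 0`` with ``a**2 + b**2 == 1``.

    The sign is canonicalised so that the first nonzero of ``(a, b)`` is
    positive, making equality comparisons between lines well-defined.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        norm = math.hypot(self.a, self.b)
        if norm < _DEGENERATE_SEP:
            raise GeometryError("line coefficients (a, b) are both ~0")
        a, b, c = self.a / norm, self.b / norm, self.c / norm
        if a < 0 or (a == 0 and b < 0):
            a, b, c = -a, -b, -c
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)

    def signed_distance(self, p) -> float:
        return self.a * p.x + self.b * p.y + self.c


def line_through(p, q) -> Line2D:
    """Normalized line through two distinct points.

    Raises :class:`GeometryError` when the points coincide (separation
    below 1e-9 in the points' own units).
    """
    dx, dy = q.x - p.x, q.y - p.y
    if math.hypot(dx, dy) <= _DEGENERATE_SEP:
        raise GeometryError(f"cannot build a line through coincident points {p} and {q}")
    # direction (dx, dy) -> normal (dy, -dx)
    a, b = dy, -dx
    c = -(a * p.x + b * p.y)
    return Line2D(a, b, c)


def project_point_to_line(p, line: Line2D):
    """Perpendicular foot of ``p`` on ``line``.

    With a normalized line the foot of the head point on the floor line is

        x1 = b*(b*x0 - a*y0) - a*c,   y1 = a*(-b*x0 + a*y0) - b*c,

    the closest point on the line to ``p``.  The returned point is of the
    same type as ``p`` (image or world).
    """
    a, b, c = line.a, line.b, line.c
    x1 = b * (b * p.x - a * p.y) - a * c
    y1 = a * (-b * p.x + a * p.y) - b * c
    return type(p)(x1, y1)


def euclidean(p, q) -> float:
    """Euclidean distance between two points of the same coordinate system."""
    return math.hypot(p.x - q.x, p.y - q.y)
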