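"""Reference-object back-end: pixel-to-millimetre conversion via a sheet
of known physical size placed in the participant plane.

The conversion deliberately avoids camera parameters: it works on the
original (distorted) photo.  Vertical pixel distances are scaled by
``h_mm / h_pi`` where ``h_pi`` is the sheet height in pixels measured
between the extrapolated top and bottom edge lines at the abscissa of the
segment; horizontal distances are scaled analogously by ``w_mm / w_pi``
using the extrapolated left and right edge lines.  The metric length of an
oblique segment is the root-sum-square of its separately converted
vertical and horizontal components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .geometry import ImagePoint

__all__ = ["ReferenceObject", "ReferenceScaleError", "ref_height_px_at", "ref_width_px_at", "distance_mm"]

#: Physical size of the study's reference sheet (portrait A0-like poster), mm.
DEFAULT_WIDTH_MM = 840.0
DEFAULT_HEIGHT_MM = 1186.0


class ReferenceScaleError(ValueError):
    """Raised for degenerate reference-object annotations."""


def _cross(o: ImagePoint, a: ImagePoint, b: ImagePoint) -> float:
    return (a.x - o.x) * (b.y - o.y) - (a.y - o.y) * (b.x - o.x)


def _segments_cross(a: ImagePoint, b: ImagePoint, c: ImagePoint, d: ImagePoint) -> bool:
    """Proper intersection test for open segments a-b and c-d."""
    d1, d2 = _cross(a, b, c), _cross(a, b, d)
    d3, d4 = _cross(c, d, a), _cross(c, d, b)
    return (d1 * d2 < 0) and (d3 * d4 < 0)


@dataclass(frozen=True)
class ReferenceObject:
    """Four annotated corners of the reference sheet plus its physical size.

    Corners are in original (distorted) image coordinates; ``tl``/``tr``/
    ``bl``/``br`` name the physical sheet corners, not image extremes.
    """

    tl: ImagePoint
    tr: ImagePoint
    bl: ImagePoint
    br: ImagePoint
    width_mm: float = DEFAULT_WIDTH_MM
    height_mm: float = DEFAULT_HEIGHT_MM

    def __post_init__(self) -> None:
        if not (self.width_mm > 0 and self.height_mm > 0):
            raise ReferenceScaleError("reference sheet dimensions must be positive")
        # simple-quadrilateral check: opposite edges of tl->tr->br->bl must not cross
        if _segments_cross(self.tl, self.tr, self.br, self.bl) or _segments_cross(
            self.tr, self.br, self.bl, self.tl
        ):
            raise ReferenceScaleError("reference corners form a self-intersecting quadrilateral")


def _gap_at(coord: float, p1: ImagePoint, p2: ImagePoint, q1: ImagePoint, q2: ImagePoint, *, vertical: bool) -> float:
    """Gap between lines p1p2 and q1q2 along the vertical (or horizontal) line at coord."""
    if vertical:
        d1, d2 = p2.x - p1.x, q2.x - q1.x
        if abs(d1) < 1e-12 or abs(d2) < 1e-12:
            raise ReferenceScaleError("reference edge line is vertical; cannot evaluate height gap")
        y_top = p1.y + (coord - p1.x) * (p2.y - p1.y) / d1
        y_bot = q1.y + (coord - q1.x) * (q2.y - q1.y) / d2
        return y_bot - y_top
    d1, d2 = p2.y - p1.y, q2.y - q1.y
    if abs(d1) < 1e-12 or abs(d2) < 1e-12:
        raise ReferenceScaleError("reference edge line is horizontal; cannot evaluate width gap")
    x_left = p1.x + (coord - p1.y) * (p2.x - p1.x) / d1
    x_right = q1.x + (coord - q1.y) * (q2.x - q1.x) / d2
    return x_right - x_left


def ref_height_px_at(x: float, ref: ReferenceObject) -> float:
    """Sheet height h_pi in pixels at image abscissa ``x``.

    The top (tl-tr) and bottom (bl-br) edge lines are extrapolated and the
    vertical gap between them is measured along the vertical line at ``x``.
    """
    gap = _gap_at(x, ref.tl, ref.tr, ref.bl, ref.br, vertical=True)
    if gap <= 0:
        raise ReferenceScaleError(f"non-positive reference height {gap:.3g} px at x={x} (corner mislabeling?)")
    return gap


def ref_width_px_at(y: float, ref: ReferenceObject) -> float:
    """Sheet width w_pi in pixels at image ordinate ``y`` (left/right edges extrapolated)."""
    gap = _gap_at(y, ref.tl, ref.bl, ref.tr, ref.br, vertical=False)
    if gap <= 0:
        raise ReferenceScaleError(f"non-positive reference width {gap:.3g} px at y={y} (corner mislabeling?)")
    return gap


def distance_mm(p: ImagePoint, q: ImagePoint, ref: ReferenceObject) -> float:
    """Metric length of the image segment p-q using the reference sheet.

    |dy| px is converted with h_mm/h_pi evaluated at the segment's midpoint
    abscissa, |dx| px with w_mm/w_pi at the midpoint ordinate, and the two
    metric components are combined as sqrt(v**2 + h**2).  For an oblique
    segment the midpoint is the symmetric choice of evaluation position.
    """
    dy = abs(q.y - p.y)
    dx = abs(q.x - p.x)
    v_mm = 0.0
    if dy > 0:
        v_mm = dy * ref.height_mm / ref_height_px_at((p.x + q.x) / 2.0, ref)
    h_mm = 0.0
    if dx > 0:
        h_mm = dx * ref.width_mm / ref_width_px_at((p.y + q.y) / 2.0, ref)
    return math.hypot(v_mm, h_mm)
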