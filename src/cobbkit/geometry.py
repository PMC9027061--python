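"""Landmark-based Cobb angle geometry.

The Cobb angle of a scoliotic curve is the angle between the cranial
endplate of the most tilted vertebra above the apex and the caudal
endplate of the most tilted vertebra below it.  Digitally, each endplate
is a straight line through two observer-placed landmarks; the software's
job is to compute endplate tilts, pick the most tilted candidate
vertebrae automatically, and report the angle between the chosen pair.

Coordinate convention: image pixel coordinates, origin at the top-left
corner, x grows rightward (columns), y grows downward (rows).  Sub-pixel
(continuous) positions are allowed.  A positive tilt means the endplate
descends left-to-right on screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "Landmark",
    "EndplateLine",
    "CurveMeasurement",
    "DegenerateGeometryError",
    "endplate_tilt",
    "cobb_between",
    "select_most_tilted",
    "measure_curve",
    "round_half_away",
]

#: Candidate roles for an endplate line.
CRANIAL = "cranial_candidate"
CAUDAL = "caudal_candidate"

#: |tilt| ties closer than this are broken by listing order.
_TIE_EPS = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when landmark geometry does not define a line."""


@dataclass(frozen=True)
class Landmark:
    """A continuous image-space point (x = column, y = row, pixels)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("landmark coordinates must be finite")


@dataclass(frozen=True)
class EndplateLine:
    """One vertebral endplate defined by two landmarks.

    Parameters
    ----------
    vertebra:
        Vertebra label, e.g. ``"T6"``.
    role:
        ``"cranial_candidate"`` or ``"caudal_candidate"``.
    p1, p2:
        The two landmarks; must be distinct.
    """

    vertebra: str
    role: str
    p1: Landmark
    p2: Landmark

    def __post_init__(self) -> None:
        if self.role not in (CRANIAL, CAUDAL):
            raise ValueError(f"unknown endplate role: {self.role!r}")
        if self.p1.x == self.p2.x and self.p1.y == self.p2.y:
            raise DegenerateGeometryError(
                f"endplate {self.vertebra}: landmarks coincide at "
                f"({self.p1.x}, {self.p1.y})"
            )
        if self.p1.x == self.p2.x:
            # endplates are near-horizontal structures: |tilt| < 90
            raise DegenerateGeometryError(
                f"endplate {self.vertebra}: landmarks define a vertical line"
            )


@dataclass(frozen=True)
class CurveMeasurement:
    """The Cobb angle of one curve with the auto-selected end vertebrae.

    ``cobb_deg`` is rounded half-away-from-zero to one decimal place,
    matching the instrument's reporting scale; ``tilts`` records the
    signed tilt of every candidate endplate considered.
    """

    curve_id: str
    cranial_vertebra: str
    caudal_vertebra: str
    cobb_deg: float
    tilts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cobb_deg < 0:
            raise ValueError("Cobb angle cannot be negative")


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (2.25 -> 2.3, -2.25 -> -2.3)."""
    q = 10.0**decimals
    return math.copysign(math.floor(abs(value) * q + 0.5), value) / q


def _scaled(p: Landmark, pixel_spacing: tuple[float, float] | None) -> tuple[float, float]:
    # pixel_spacing is (row_mm, col_mm): y scales by rows, x by columns
    if pixel_spacing is None:
        return p.x, p.y
    row_mm, col_mm = pixel_spacing
    if row_mm <= 0 or col_mm <= 0:
        raise ValueError("pixel spacing must be strictly positive")
    return p.x * col_mm, p.y * row_mm


def endplate_tilt(
    line: EndplateLine, pixel_spacing: tuple[float, float] | None = None
) -> float:
    """Signed tilt of an endplate line w.r.t. the image horizontal.

    Returns the angle in degrees in (-90, 90], positive when the line
    descends left-to-right on screen (y-down convention).  Invariant
    under swapping the two landmarks and under uniform scaling.

    With anisotropic ``pixel_spacing`` (row mm/px, col mm/px) the
    landmarks are mapped to physical millimetres first, since angles
    measured on non-square pixels are otherwise distorted.
    """
    x1, y1 = _scaled(line.p1, pixel_spacing)
    x2, y2 = _scaled(line.p2, pixel_spacing)
    dx, dy = x2 - x1, y2 - y1
    if dx == 0.0 and dy == 0.0:
        raise DegenerateGeometryError("coincident landmarks")
    theta = math.degrees(math.atan2(dy, dx))
    # lines are undirected: fold into (-90, 90]
    if theta > 90.0:
        theta -= 180.0
    elif theta <= -90.0:
        theta += 180.0
    return theta


def cobb_between(
    cranial: EndplateLine,
    caudal: EndplateLine,
    pixel_spacing: tuple[float, float] | None = None,
) -> float:
    """Unrounded Cobb angle between two endplate lines, in [0, 180).

    Equals the classical angle between the perpendiculars dropped from
    the two endplates; 0 for parallel lines; symmetric in its arguments.
    """
    return abs(
        endplate_tilt(cranial, pixel_spacing) - endplate_tilt(caudal, pixel_spacing)
    )


def select_most_tilted(
    cranial_candidates: Sequence[EndplateLine],
    caudal_candidates: Sequence[EndplateLine],
    pixel_spacing: tuple[float, float] | None = None,
) -> tuple[EndplateLine, EndplateLine]:
    """Pick the candidate with maximum absolute tilt from each list.

    This reproduces the end-vertebra selection rule: the end vertebrae
    are the ones most inclined to the horizontal.  Ties within 1e-9
    degrees are broken by listing order (the observer's selection
    order), making the choice deterministic.
    """
    if not cranial_candidates or not caudal_candidates:
        raise ValueError("each candidate list must be non-empty")

    def pick(lines: Sequence[EndplateLine]) -> EndplateLine:
        best = lines[0]
        best_t = abs(endplate_tilt(best, pixel_spacing))
        for line in lines[1:]:
            t = abs(endplate_tilt(line, pixel_spacing))
            if t > best_t + _TIE_EPS:
                best, best_t = line, t
        return best

    return pick(cranial_candidates), pick(caudal_candidates)


def measure_curve(
    curve_id: str,
    cranial_candidates: Sequence[EndplateLine],
    caudal_candidates: Sequence[EndplateLine],
    pixel_spacing: tuple[float, float] | None = None,
) -> CurveMeasurement:
    """Measure one curve: select end vertebrae, compute the Cobb angle.

    The angle is rounded half-away-from-zero to one decimal place only
    here, at measurement construction — intermediate geometry stays at
    full precision.
    """
    cranial, caudal = select_most_tilted(
        cranial_candidates, caudal_candidates, pixel_spacing
    )
    angle = cobb_between(cranial, caudal, pixel_spacing)
    tilts = {
        line.vertebra: endplate_tilt(line, pixel_spacing)
        for line in (*cranial_candidates, *caudal_candidates)
    }
    return CurveMeasurement(
        curve_id=curve_id,
        cranial_vertebra=cranial.vertebra,
        caudal_vertebra=caudal.vertebra,
        cobb_deg=round_half_away(angle, 1),
        tilts=tilts,
    )
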