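"""Geometric core: zones, quadrants, crypt size, angular coverage, iris width.

The three annotation circles are drawn independently and need not be
concentric, so zone and extension computations intersect rays cast from the
user-defined iris centre with each circle rather than comparing radii.

Angles come in two frames:

* image angles — degrees measured from the image +x axis toward +y
  (downward), used for raw ray casting;
* anatomical angles — degrees from the nasal axis toward superior, used for
  quadrant logic. The mapping depends on eye side and mirroring (see
  :func:`anatomical_to_image_angle`).
"""

from __future__ import annotations

import math
import warnings
from enum import Enum
from typing import Sequence

from .annotation import (
    ArcInterval,
    Circle,
    CryptMark,
    FeatureObservation,
    IrisAnnotation,
    Point,
)
from .errors import ValidationError

__all__ = [
    "Zone",
    "CryptSize",
    "ray_circle_distance",
    "zone_of_point",
    "quadrant_of_point",
    "ciliary_extension_fraction",
    "classify_crypt",
    "angular_union_degrees",
    "arcs_to_observation",
    "iris_width",
    "anatomical_angle_of_point",
    "anatomical_to_image_angle",
    "QUADRANT_SECTORS",
]


class Zone(Enum):
    PUPIL = "pupil"
    PUPILLARY_ZONE = "pupillary_zone"
    CILIARY_ZONE = "ciliary_zone"
    OUTSIDE = "outside"


class CryptSize(Enum):
    LARGE = "large"
    SMALL = "small"


def ray_circle_distance(origin: Point, angle_deg: float, circle: Circle) -> float:
    """Distance along the ray from `origin` at `angle_deg` (image frame) to
    its unique forward crossing of `circle`.

    The origin must lie strictly inside the circle so that exactly one
    positive crossing exists.
    """
    dx = origin.x - circle.centre.x
    dy = origin.y - circle.centre.y
    d2 = dx * dx + dy * dy
    if d2 >= circle.radius * circle.radius:
        raise ValidationError(
            "ray origin lies on or outside the circle; no unique forward crossing"
        )
    theta = math.radians(angle_deg)
    ux, uy = math.cos(theta), math.sin(theta)
    b = ux * dx + uy * dy
    # |o + t u - c|^2 = r^2  =>  t^2 + 2bt + (d2 - r^2) = 0
    disc = b * b - (d2 - circle.radius * circle.radius)
    return -b + math.sqrt(disc)


# Quadrant layout in the anatomical frame (angle from nasal toward superior):
# Q1 upper-nasal [0,90), Q4 upper-temporal [90,180), Q3 lower-temporal
# [180,270), Q2 lower-nasal [270,360). Half-open sectors break ties.
QUADRANT_SECTORS: dict[int, tuple[float, float]] = {
    1: (0.0, 90.0),
    4: (90.0, 180.0),
    3: (180.0, 270.0),
    2: (270.0, 360.0),
}


def _nasal_sign(a: IrisAnnotation) -> float:
    sign = 1.0 if a.eye_side.value == "right" else -1.0
    if a.mirrored:
        sign = -sign
    return sign


def anatomical_angle_of_point(a: IrisAnnotation, p: Point) -> float:
    """Anatomical angle (degrees in [0,360)) of `p` seen from the iris centre."""
    dx = p.x - a.iris_centre.x
    dy = p.y - a.iris_centre.y
    if dx == 0.0 and dy == 0.0:
        raise ValidationError("point coincides with the iris centre")
    nasal = _nasal_sign(a) * dx
    superior = -dy  # image y grows downward
    return math.degrees(math.atan2(superior, nasal)) % 360.0


def anatomical_to_image_angle(a: IrisAnnotation, phi_deg: float) -> float:
    """Image-frame angle of the direction at anatomical angle `phi_deg`."""
    phi = math.radians(phi_deg)
    dx = _nasal_sign(a) * math.cos(phi)
    dy = -math.sin(phi)
    return math.degrees(math.atan2(dy, dx)) % 360.0


def _ray_distances(a: IrisAnnotation, p: Point) -> tuple[float, float, float, float]:
    """(|p-centre|, d_pupil, d_collarette, d_sclera) along the centre->p ray."""
    dx = p.x - a.iris_centre.x
    dy = p.y - a.iris_centre.y
    dist = math.hypot(dx, dy)
    angle = math.degrees(math.atan2(dy, dx))
    dp = ray_circle_distance(a.iris_centre, angle, a.pupil_circle)
    dc = ray_circle_distance(a.iris_centre, angle, a.collarette_circle)
    ds = ray_circle_distance(a.iris_centre, angle, a.sclera_circle)
    return dist, dp, dc, ds


def zone_of_point(a: IrisAnnotation, p: Point) -> Zone:
    """Classify `p` into pupil / pupillary zone / ciliary zone / outside."""
    if p.x == a.iris_centre.x and p.y == a.iris_centre.y:
        return Zone.PUPIL
    dist, dp, dc, ds = _ray_distances(a, p)
    if dist < dp:
        return Zone.PUPIL
    if dist < dc:
        return Zone.PUPILLARY_ZONE
    if dist < ds:
        return Zone.CILIARY_ZONE
    return Zone.OUTSIDE


def quadrant_of_point(a: IrisAnnotation, p: Point) -> int:
    """Quadrant (1..4) of `p`; Q1 is upper nasal, numbering per the sectors."""
    phi = anatomical_angle_of_point(a, p)
    for quad, (lo, hi) in QUADRANT_SECTORS.items():
        if lo <= phi < hi:
            return quad
    raise AssertionError("unreachable: angle normalized to [0,360)")


def ciliary_extension_fraction(a: IrisAnnotation, p: Point) -> float:
    """Fraction of the ciliary-zone depth reached by `p` along its ray.

    0 at (or inside) the collarette, 1 at (or beyond) the scleral boundary;
    clamped to [0, 1]. Points beyond the sclera circle raise a warning and
    clamp rather than fail, tolerating annotation noise.
    """
    if p.x == a.iris_centre.x and p.y == a.iris_centre.y:
        return 0.0
    dist, _, dc, ds = _ray_distances(a, p)
    if ds <= dc:
        raise ValidationError(
            "degenerate ciliary zone: sclera does not lie beyond the collarette"
        )
    if dist > ds:
        warnings.warn(
            "point lies outside the sclera circle; extension clamped to 1.0",
            stacklevel=2,
        )
    f = (dist - dc) / (ds - dc)
    return min(1.0, max(0.0, f))


def classify_crypt(a: IrisAnnotation, c: CryptMark) -> CryptSize:
    """LARGE iff the crypt originates from the collarette and its tip extends
    into strictly more than 50% of the ciliary zone; otherwise SMALL.

    The 50% boundary is a strict inequality: a tip at exactly half depth is
    SMALL. Crypts not originating from the collarette are small by fiat.
    """
    if not c.from_collarette:
        return CryptSize.SMALL
    f = ciliary_extension_fraction(a, c.tip)
    return CryptSize.LARGE if f > 0.5 else CryptSize.SMALL


def _canonical_segments(arcs: Sequence[ArcInterval]) -> list[tuple[float, float]]:
    """Split wraparound arcs so every segment satisfies start < end."""
    segs = []
    for arc in arcs:
        if arc.end_deg > arc.start_deg:
            segs.append((arc.start_deg, arc.end_deg))
        else:
            segs.append((arc.start_deg, 360.0))
            if arc.end_deg > 0.0:
                segs.append((0.0, arc.end_deg))
    return segs


def _merged_union(arcs: Sequence[ArcInterval]) -> list[tuple[float, float]]:
    segs = sorted(_canonical_segments(arcs))
    merged: list[tuple[float, float]] = []
    for lo, hi in segs:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def angular_union_degrees(arcs: Sequence[ArcInterval]) -> float:
    """Measure (degrees in [0, 360]) of the union of the arcs."""
    return sum(hi - lo for lo, hi in _merged_union(arcs))


def arcs_to_observation(arcs: Sequence[ArcInterval]) -> FeatureObservation:
    """Summarize angular arcs as a presence/extension observation.

    ``over_180`` is strict (> 180 exactly); quadrant flags require the union
    to overlap the sector with positive measure, so touching a boundary does
    not set a flag.
    """
    merged = _merged_union(arcs)
    union = sum(hi - lo for lo, hi in merged)
    if union == 0.0:
        return FeatureObservation.absent()
    quadrants = []
    for q in range(1, 5):
        lo_s, hi_s = QUADRANT_SECTORS[q]
        overlap = sum(
            max(0.0, min(hi, hi_s) - max(lo, lo_s)) for lo, hi in merged
        )
        quadrants.append(overlap > 0.0)
    return FeatureObservation(True, union > 180.0, tuple(quadrants))


def iris_width(a: IrisAnnotation) -> float:
    """Iris width in pixels: the diameter of the scleral best-fit circle."""
    return 2.0 * a.sclera_circle.radius
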