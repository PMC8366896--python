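"""Right-angle mixture triangle (RMT) geometry.

An RMT represents a three-component mixture as a 2-D Cartesian point: the
x-axis carries the highly digestible macronutrients (TNC+lipids), the y-axis
available protein, and the third component (cellulose + hemicellulose,
"fiber") is implicit as ``i = 100 - x - y``.  Distance from the hypotenuse
x + y = 100 therefore reads as fiber content.  Lignin and ash are excluded
from the macronutrient total before projection.

The convex hull of a set of mixture points is the "nutritional space" an
animal mixing those foods can reach.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .composition import MacronutrientProfile

__all__ = [
    "RMTPoint",
    "NutritionalSpace",
    "to_rmt",
    "to_rmt_xy",
    "balance_ratio",
    "observed_range",
    "nutritional_space",
]

#: Profiles whose macronutrient total falls below this are degenerate.
_MACRO_FLOOR = 1e-9


@dataclass(frozen=True)
class RMTPoint:
    """A three-component mixture as % of the macronutrient total.

    ``x`` = TNC+lipids, ``y`` = available protein, ``i`` = fiber (implicit:
    100 - x - y).  Coordinates are non-negative and sum to 100.
    """

    x: float
    y: float
    source_kind: str = "rumen"

    @property
    def i(self) -> float:
        return 100.0 - self.x - self.y

    def __post_init__(self) -> None:
        if self.x < -1e-9 or self.y < -1e-9 or self.x + self.y > 100.0 + 1e-9:
            raise ValueError(f"invalid RMT coordinates ({self.x}, {self.y})")


def to_rmt(profile: MacronutrientProfile) -> RMTPoint:
    """Project a macronutrient profile into the mixture triangle.

    Each of (TNC, AP, fiber) is expressed as a percentage of their sum;
    lignin and ash do not enter the denominator.  Rumen profiles use
    TNC2+lipids on the x-axis, plant profiles TNC1 + lipids.
    """
    if profile.source_kind == "rumen":
        tnc = profile.tnc2_lipids
        if tnc is None:
            raise ValueError(f"sample {profile.sample_id!r}: no TNC2+lipids")
    else:
        if profile.tnc1 is None:
            raise ValueError(f"sample {profile.sample_id!r}: no TNC1")
        tnc = profile.tnc1 + (profile.lipids or 0.0)
    return to_rmt_xy(profile.ap, profile.fiber, tnc,
                     source_kind=profile.source_kind)


def to_rmt_xy(ap: float, fiber: float, tnc: float, *,
              source_kind: str = "rumen") -> RMTPoint:
    """Projection from raw (AP, fiber, TNC) amounts; scale invariant."""
    total = ap + fiber + tnc
    if total <= _MACRO_FLOOR:
        raise ValueError("zero macronutrient total, projection undefined")
    if min(ap, fiber, tnc) < 0:
        raise ValueError(f"negative macronutrient in ({ap}, {fiber}, {tnc})")
    return RMTPoint(x=100.0 * tnc / total, y=100.0 * ap / total,
                    source_kind=source_kind)


def balance_ratio(p: RMTPoint) -> float:
    """Protein-to-digestible-energy balance: y / x (AP over TNC+lipids)."""
    if p.x <= 0:
        raise ValueError("balance ratio undefined at x = 0")
    return p.y / p.x


def observed_range(points: Iterable[RMTPoint]) -> dict[str, tuple[float, float]]:
    """Elementwise (min, max) of the x, y and implicit axes."""
    pts = list(points)
    if not pts:
        raise ValueError("observed_range of an empty collection")
    xs = [p.x for p in pts]
    ys = [p.y for p in pts]
    iz = [p.i for p in pts]
    return {"x": (min(xs), max(xs)),
            "y": (min(ys), max(ys)),
            "i": (min(iz), max(iz))}


@dataclass(frozen=True)
class NutritionalSpace:
    """Convex hull of mixture points in the (x, y) plane.

    ``vertices`` are in counter-clockwise order starting from the
    lexicographically smallest vertex; ``area`` is in squared %-units.
    A degenerate input (< 3 points, or all collinear) yields area 0.
    """

    vertices: tuple[tuple[float, float], ...]
    area: float

    def contains(self, p: RMTPoint, *, tol: float = 1e-9) -> bool:
        """Point-in-convex-polygon test (boundary counts as inside)."""
        v = np.asarray(self.vertices)
        if len(v) < 3:
            # degenerate: membership means lying on the segment/point
            if len(v) == 0:
                return False
            d = np.hypot(v[:, 0] - p.x, v[:, 1] - p.y)
            if d.min() <= tol:
                return True
            if len(v) == 2:
                a, b = v
                ab = b - a
                t = np.dot([p.x - a[0], p.y - a[1]], ab) / np.dot(ab, ab)
                t = min(1.0, max(0.0, t))
                proj = a + t * ab
                return bool(np.hypot(proj[0] - p.x, proj[1] - p.y) <= tol)
            return False
        # CCW polygon: point is inside iff every edge cross product >= 0
        nxt = np.roll(v, -1, axis=0)
        cross = ((nxt[:, 0] - v[:, 0]) * (p.y - v[:, 1])
                 - (nxt[:, 1] - v[:, 1]) * (p.x - v[:, 0]))
        return bool((cross >= -tol).all())


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def nutritional_space(points: Iterable[RMTPoint]) -> NutritionalSpace:
    """Convex hull of the points in the (x, y) plane with shoelace area."""
    pts = np.array([[p.x, p.y] for p in points], dtype=float)
    if len(pts) == 0:
        return NutritionalSpace(vertices=(), area=0.0)
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 3:
        return NutritionalSpace(vertices=tuple(map(tuple, uniq)), area=0.0)
    try:
        hull = ConvexHull(uniq)
    except QhullError:  # all collinear
        order = np.lexsort((uniq[:, 1], uniq[:, 0]))
        ends = uniq[[order[0], order[-1]]]
        return NutritionalSpace(vertices=tuple(map(tuple, ends)), area=0.0)
    verts = uniq[hull.vertices]  # CCW for 2-D qhull
    start = np.lexsort((verts[:, 1], verts[:, 0]))[0]
    verts = np.roll(verts, -start, axis=0)
    return NutritionalSpace(vertices=tuple(map(tuple, verts)),
                            area=_shoelace(verts))
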