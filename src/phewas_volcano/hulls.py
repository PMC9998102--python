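"""From-scratch 2-D convex-hull geometry for grouping traits by category.

A convex hull is the smallest convex polygon containing a point set; drawn
per trait category it shifts visual attention from individual phenotypes to
groups of related ones.  The construction is Andrew's monotone chain with
exact lexicographic tie-breaking, emitting a canonical counter-clockwise
vertex order so hulls are directly comparable in tests.  Note a hull may
legitimately span the beta = 0 line (a category can contain both risk and
protective associations); nothing here clips at zero effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

__all__ = [
    "Point2D",
    "HullPolygon",
    "convex_hull",
    "category_hulls",
    "expand_hull",
    "polygon_area",
    "point_in_polygon",
]


@dataclass(frozen=True, order=True)
class Point2D:
    """A point in plot space: x = effect size, y = -log10 P."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")


@dataclass(frozen=True)
class HullPolygon:
    """A strictly convex polygon enclosing one category's displayed points.

    Vertices are counter-clockwise starting at the lexicographically
    smallest vertex; no three consecutive vertices are collinear.
    ``padding`` records any display-space expansion already applied.
    """

    category: str
    vertices: tuple[Point2D, ...]
    padding: float = 0.0

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("a hull polygon needs at least 3 vertices")
        if self.padding < 0:
            raise ValueError(f"padding must be >= 0, got {self.padding}")

    @property
    def area(self) -> float:
        return polygon_area(self.vertices)

    def centroid(self) -> Point2D:
        """Vertex mean — an interior point of any convex polygon."""
        n = len(self.vertices)
        return Point2D(
            sum(v.x for v in self.vertices) / n,
            sum(v.y for v in self.vertices) / n,
        )


def _cross(o: Point2D, a: Point2D, b: Point2D) -> float:
    """z of (a-o) x (b-o): >0 for a left (counter-clockwise) turn."""
    return (a.x - o.x) * (b.y - o.y) - (a.y - o.y) * (b.x - o.x)


def convex_hull(points: Iterable[Point2D]) -> Optional[tuple[Point2D, ...]]:
    """Minimal convex polygon around ``points`` (monotone-chain construction).

    Returns the hull vertices in canonical order (counter-clockwise from the
    lexicographically smallest vertex), collinear boundary points dropped so
    the polygon is strictly convex.  Returns None when the input has fewer
    than 3 distinct points or is entirely collinear — such sets bound no
    polygon.  Vertices are always a subset of the inputs.
    """
    pts = sorted(set(points))
    if len(pts) < 3:
        return None

    def half(seq: Sequence[Point2D]) -> list[Point2D]:
        chain: list[Point2D] = []
        for p in seq:
            # <= 0 pops collinear points: strict convexity
            while len(chain) >= 2 and _cross(chain[-2], chain[-1], p) <= 0:
                chain.pop()
            chain.append(p)
        return chain

    lower = half(pts)
    upper = half(pts[::-1])
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:  # all points collinear
        return None
    # lower-then-upper is CCW and starts at the lexicographic minimum
    return tuple(hull)


def category_hulls(
    points: Sequence[tuple[Point2D, str]],
    min_points: int = 3,
) -> list[HullPolygon]:
    """One hull per category with enough non-degenerate points.

    Categories with fewer than ``min_points`` distinct points, or whose
    points are all collinear, produce no hull (a zero-area segment would be
    an invisible or misleading mark).  Output sorted by category label.
    """
    if min_points < 3:
        raise ValueError(f"min_points must be >= 3, got {min_points}")
    by_cat: dict[str, list[Point2D]] = {}
    for pt, cat in points:
        by_cat.setdefault(cat, []).append(pt)
    out: list[HullPolygon] = []
    for cat in sorted(by_cat):
        pts = by_cat[cat]
        if len(set(pts)) < min_points:
            continue
        verts = convex_hull(pts)
        if verts is None:
            continue
        out.append(HullPolygon(category=cat, vertices=verts))
    return out


def expand_hull(h: HullPolygon, padding: float) -> HullPolygon:
    """Pad a hull outward for visual breathing room around its points.

    Each vertex moves away from the polygon's vertex centroid by exactly
    ``padding`` display units along the normalized centroid-to-vertex
    direction.  Every original vertex lies on the segment from the centroid
    to its moved image, and the centroid is a convex combination of the
    moved vertices, so the original polygon is contained in the expanded
    one.
    """
    if padding < 0:
        raise ValueError(f"padding must be >= 0, got {padding}")
    if padding == 0:
        return h
    c = h.centroid()
    moved = []
    for v in h.vertices:
        dx, dy = v.x - c.x, v.y - c.y
        norm = math.hypot(dx, dy)
        if norm == 0:  # cannot happen for a strictly convex polygon
            moved.append(v)
            continue
        moved.append(Point2D(v.x + padding * dx / norm, v.y + padding * dy / norm))
    return HullPolygon(category=h.category, vertices=tuple(moved), padding=h.padding + padding)


def polygon_area(vertices: Sequence[Point2D]) -> float:
    """Shoelace area; positive for counter-clockwise vertex order."""
    n = len(vertices)
    acc = 0.0
    for i in range(n):
        a, b = vertices[i], vertices[(i + 1) % n]
        acc += a.x * b.y - b.x * a.y
    return 0.5 * acc


def point_in_polygon(p: Point2D, vertices: Sequence[Point2D], eps: float = 1e-12) -> bool:
    """Is ``p`` inside or on the boundary of a CCW convex polygon?"""
    n = len(vertices)
    for i in range(n):
        a, b = vertices[i], vertices[(i + 1) % n]
        if (b.x - a.x) * (p.y - a.y) - (b.y - a.y) * (p.x - a.x) < -eps:
            return False
    return True
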