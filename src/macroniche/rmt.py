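"""Right-angled mixture triangle (RMT) geometry and niche breadth.

A three-part macronutrient profile (P + L + C = 100) is plotted in 2D by
taking two components as explicit axes; the third is implicit
(100 − x − y), so compositions live in the right triangle with legs on the
axes.  Niche breadth for a food set is the area of the convex hull of its
food points; breadths are compared between groups as a ratio ≥ 1
("relative effect size").

Because profile points lie on the plane x + y + z = 100, each of the three
coordinate projections scales in-plane areas by the same factor, so hull
areas — and hence breadth ratios — do not depend on which pair of
macronutrients is chosen as the axes.

The hull is built with Andrew's monotone chain (deterministic output:
counter-clockwise vertices starting from the lexicographic minimum,
collinear edge points excluded) and the area by the shoelace formula, the
classic ``chull``/``areapl`` pairing of spatial point-pattern analysis.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

from .types import MacronutrientProfile, ValidationError

__all__ = [
    "RMTPoint",
    "NicheHull",
    "to_rmt",
    "convex_hull",
    "hull_area",
    "breadth_ratio",
    "food_hull",
    "DEFAULT_AXES",
]

#: Default explicit axes: x = carbohydrate %, y = protein % (lipid implicit).
DEFAULT_AXES = ("C", "P")

_GEOM_EPS = 1e-9


@dataclass(frozen=True)
class RMTPoint:
    """One composition in RMT coordinates: two explicit axes + implicit rest."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x < -_GEOM_EPS or self.y < -_GEOM_EPS:
            raise ValidationError(f"RMT coordinates negative: ({self.x}, {self.y})")
        if self.x + self.y > 100.0 + 1e-6:
            raise ValidationError(
                f"RMT point outside simplex: x + y = {self.x + self.y:.4f} > 100"
            )

    @property
    def implicit(self) -> float:
        """The implicit third component, 100 − x − y."""
        return 100.0 - self.x - self.y

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class NicheHull:
    """Convex hull of a group's food points: ordered vertices + area.

    ``vertices`` are counter-clockwise starting from the lexicographic
    minimum; ``degenerate`` marks hulls of <3 distinct non-collinear points
    (area 0).
    """

    label: str
    vertices: tuple[RMTPoint, ...]
    area: float
    n_points: int
    degenerate: bool = False


def to_rmt(
    profile: MacronutrientProfile,
    axes: Sequence[str] = DEFAULT_AXES,
) -> RMTPoint:
    """Project a profile to RMT coordinates.

    ``axes`` names the two explicit macronutrients (one-letter P/L/C or full
    names), in (x, y) order; the remaining macronutrient is implicit.

    Raises
    ------
    ValidationError
        If the two axes name the same macronutrient.
    """
    if len(axes) != 2:
        raise ValidationError(f"need exactly two axes, got {axes!r}")
    ax, ay = (a.strip().upper()[0] for a in axes)
    if ax == ay:
        raise ValidationError(f"duplicate RMT axes {axes!r}")
    return RMTPoint(profile.component(ax), profile.component(ay))


def _cross(o: tuple[float, float], a: tuple[float, float], b: tuple[float, float]) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _monotone_chain(pts: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Andrew's monotone chain; strictly convex vertices, CCW order."""
    pts = sorted(set(pts))
    if len(pts) <= 2:
        return pts
    lower: list[tuple[float, float]] = []
    for p in pts:
        while len(lower) >= 2 and _cross(lower[-2], lower[-1], p) <= _GEOM_EPS:
            lower.pop()
        lower.append(p)
    upper: list[tuple[float, float]] = []
    for p in reversed(pts):
        while len(upper) >= 2 and _cross(upper[-2], upper[-1], p) <= _GEOM_EPS:
            upper.pop()
        upper.append(p)
    return lower[:-1] + upper[:-1]


def shoelace_area(vertices: Sequence[tuple[float, float]]) -> float:
    """Signed-free polygon area by the shoelace formula."""
    n = len(vertices)
    if n < 3:
        return 0.0
    s = 0.0
    for i in range(n):
        x0, y0 = vertices[i]
        x1, y1 = vertices[(i + 1) % n]
        s += x0 * y1 - x1 * y0
    return abs(s) / 2.0


def convex_hull(points: Iterable[RMTPoint], label: str = "") -> NicheHull:
    """Convex hull of a point set, with deterministic vertex order.

    Fewer than three distinct points, or an all-collinear set, yields a
    degenerate hull with area 0 (flagged, not an error): a group eating
    foods spanning no 2D region has zero niche breadth by this measure.
    """
    pts = list(points)
    coords = [p.as_tuple() for p in pts]
    hull = _monotone_chain(coords)
    if len(hull) < 3:
        verts = tuple(RMTPoint(*c) for c in hull)
        return NicheHull(label, verts, 0.0, len(pts), degenerate=True)
    area = shoelace_area(hull)
    return NicheHull(label, tuple(RMTPoint(*c) for c in hull), area, len(pts))


def hull_area(hull: NicheHull) -> float:
    """Polygon area of a hull (percent² units); 0 for degenerate hulls."""
    if hull.degenerate:
        return 0.0
    return shoelace_area([v.as_tuple() for v in hull.vertices])


def breadth_ratio(hull_a: NicheHull, hull_b: NicheHull) -> tuple[float, str]:
    """Relative niche-breadth effect size: (max area / min area, larger label).

    Raises
    ------
    ValidationError
        If either hull has zero area (ratio undefined).
    """
    if hull_a.area <= 0 or hull_b.area <= 0:
        raise ValidationError("breadth ratio undefined for zero-area hulls")
    if hull_a.area >= hull_b.area:
        return hull_a.area / hull_b.area, hull_a.label
    return hull_b.area / hull_a.area, hull_b.label


def food_hull(
    profiles: Iterable[MacronutrientProfile],
    label: str = "",
    axes: Sequence[str] = DEFAULT_AXES,
) -> NicheHull:
    """Niche hull of a set of food profiles under a chosen axis pair."""
    return convex_hull((to_rmt(p, axes) for p in profiles), label=label)
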