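"""Bounding-box analysis and the linear-time column min/max reduction.

The reduction preconditions a set of ``n`` 2D points with integer
coordinates, bounded by a ``p x q`` box, before a convex hull is built.
One pass over the points records, for every column ``i`` of the grid
(or every row, when scanning along ``y``), the minimum and maximum of the
other coordinate.  At most two points per column survive, so the reduced
set has ``s <= 2p`` points, a potential removal fraction of ``1 - 2p/n``.
The reduction is only worthwhile (and only linear) when ``min(p, q) <= n``;
:func:`decide` encodes that rule.

All arithmetic in this module is exact integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, NamedTuple

__all__ = [
    "Point",
    "PointSet",
    "BoundingBox",
    "PreconditionDecision",
    "ExtremesTable",
    "ReductionStats",
    "compute_bounding_box",
    "decide",
    "reduce",
    "valid_points",
    "stats",
]

Axis = Literal["x", "y"]
Mode = Literal["apply_along_x", "apply_along_y", "skip"]


class Point(NamedTuple):
    """A 2D grid point with exact integer coordinates."""

    x: int
    y: int


@dataclass
class PointSet:
    """An ordered collection of grid points; duplicates are permitted.

    ``n`` counts every point, duplicates included — the reduction itself is
    duplicate-insensitive, but reduction statistics are reported against the
    full input count.
    """

    points: list[Point] = field(default_factory=list)

    @classmethod
    def from_iterable(cls, pairs: Iterable[tuple[int, int]]) -> "PointSet":
        pts = []
        for x, y in pairs:
            xi, yi = int(x), int(y)
            if xi != x or yi != y:
                raise ValueError(f"non-integer coordinate: ({x}, {y})")
            pts.append(Point(xi, yi))
        return cls(pts)

    @property
    def n(self) -> int:
        return len(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[Point]:
        return iter(self.points)

    def __getitem__(self, i):
        return self.points[i]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned integer bounding box with side lengths ``p`` and ``q``.

    Side lengths count lattice columns/rows inclusively:
    ``p = x_max - x_min + 1`` and ``q = y_max - y_min + 1``; the box holds
    ``m = p * q`` lattice points.
    """

    x_min: int
    x_max: int
    y_min: int
    y_max: int

    def __post_init__(self) -> None:
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError("inverted bounding box")

    @property
    def p(self) -> int:
        return self.x_max - self.x_min + 1

    @property
    def q(self) -> int:
        return self.y_max - self.y_min + 1

    @property
    def m(self) -> int:
        return self.p * self.q

    def contains(self, pt: Point) -> bool:
        return self.x_min <= pt.x <= self.x_max and self.y_min <= pt.y <= self.y_max


@dataclass(frozen=True)
class PreconditionDecision:
    """Outcome of the ``min(p, q) <= n`` rule.

    ``skip`` means the data are too sparse for the reduction to pay off
    (and an extent-sized table could be huge); either apply mode names the
    scan axis with the smaller extent.
    """

    mode: Mode
    reason: str

    @property
    def axis(self) -> Axis | None:
        if self.mode == "apply_along_x":
            return "x"
        if self.mode == "apply_along_y":
            return "y"
        return None


@dataclass
class ExtremesTable:
    """Per-column (min, max) pairs — the output array ``L`` of the reduction.

    Entries are stored in translated 1-based coordinates: table index ``i``
    (1-based) corresponds to absolute scan coordinate ``origin + i - 1``, and
    an entry value ``c`` corresponds to absolute cross coordinate
    ``cross_origin + c - 1``.  Columns never touched by a point hold the
    sentinel pair ``(cross_extent + 1, -1)``, the initialization value whose
    min/max updates are identities.
    """

    axis: Axis
    origin: int
    cross_origin: int
    cross_extent: int
    entries: list[tuple[int, int]]

    @property
    def sentinel(self) -> tuple[int, int]:
        return (self.cross_extent + 1, -1)

    @property
    def extent(self) -> int:
        return len(self.entries)

    def is_sentinel(self, entry: tuple[int, int]) -> bool:
        return entry == self.sentinel


@dataclass(frozen=True)
class ReductionStats:
    """Input count, surviving count, and the analytic removal bound.

    ``theoretical_bound`` is ``max(0, 1 - 2p/n)`` where ``p`` is the scan
    extent: with at most two survivors per column, at least that fraction of
    the input is removed whenever every column is populated enough.
    """

    n: int
    s: int
    fraction_removed: float
    theoretical_bound: float


def compute_bounding_box(ps: PointSet) -> BoundingBox:
    """Exact min/max over all points; O(n) linear scan.

    Raises ``ValueError`` on an empty point set (no geometry to bound).
    """
    if len(ps) == 0:
        raise ValueError("cannot bound an empty point set")
    it = iter(ps)
    first = next(it)
    x_min = x_max = first.x
    y_min = y_max = first.y
    for pt in it:
        if pt.x < x_min:
            x_min = pt.x
        elif pt.x > x_max:
            x_max = pt.x
        if pt.y < y_min:
            y_min = pt.y
        elif pt.y > y_max:
            y_max = pt.y
    return BoundingBox(x_min, x_max, y_min, y_max)


def decide(bbox: BoundingBox, n: int) -> PreconditionDecision:
    """Apply the reduction along the smaller box side iff ``min(p, q) <= n``.

    Ties (``p == q``) resolve to the x axis.  When the condition fails the
    data are sparse (fewer points than grid columns) and the reduction is
    skipped: it would run in O(n + p) rather than O(n) and remove few points.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p, q = bbox.p, bbox.q
    if min(p, q) > n:
        return PreconditionDecision(
            "skip", f"sparse: min(p, q) = {min(p, q)} > n = {n}"
        )
    if p <= q:
        return PreconditionDecision("apply_along_x", f"p = {p} <= q = {q}, p <= n = {n}")
    return PreconditionDecision("apply_along_y", f"q = {q} < p = {p}, q <= n = {n}")


def reduce(ps: PointSet, bbox: BoundingBox, axis: Axis) -> ExtremesTable:
    """One pass over the points, tracking per-column cross-coordinate extremes.

    Each point is visited exactly once; the result is independent of input
    order and of duplicates.  Points are translated so scan and cross
    coordinates are 1-based inside the box; the offsets are kept on the
    returned table and inverted by :func:`valid_points`.

    Raises ``ValueError`` for an empty set or a point outside ``bbox``
    (inconsistent preprocessing).
    """
    if len(ps) == 0:
        raise ValueError("cannot reduce an empty point set")
    if axis == "x":
        origin, cross_origin = bbox.x_min, bbox.y_min
        extent, cross_extent = bbox.p, bbox.q
    elif axis == "y":
        origin, cross_origin = bbox.y_min, bbox.x_min
        extent, cross_extent = bbox.q, bbox.p
    else:
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")

    sentinel = (cross_extent + 1, -1)
    entries = [sentinel] * extent
    for pt in ps:
        if not bbox.contains(pt):
            raise ValueError(f"point {tuple(pt)} lies outside {bbox}")
        if axis == "x":
            i = pt.x - origin
            c = pt.y - cross_origin + 1
        else:
            i = pt.y - origin
            c = pt.x - cross_origin + 1
        u, v = entries[i]
        if c < u:
            u = c
        if c > v:
            v = c
        entries[i] = (u, v)
    return ExtremesTable(axis, origin, cross_origin, cross_extent, entries)


def _entry_points(t: ExtremesTable) -> Iterator[Point]:
    """Absolute-coordinate points of every valid entry, ascending, min first."""
    sentinel = t.sentinel
    for i, (u, v) in enumerate(t.entries):
        if (u, v) == sentinel:
            continue
        scan = t.origin + i
        lo = t.cross_origin + u - 1
        hi = t.cross_origin + v - 1
        if t.axis == "x":
            yield Point(scan, lo)
            if v != u:
                yield Point(scan, hi)
        else:
            yield Point(lo, scan)
            if v != u:
                yield Point(hi, scan)


def valid_points(t: ExtremesTable) -> PointSet:
    """The surviving points: per valid entry, its min and (if distinct) max.

    Points come out in ascending scan coordinate, min before max within a
    column, mapped back to absolute coordinates.  The count ``s`` is at most
    ``2 * extent``.
    """
    return PointSet(list(_entry_points(t)))


def stats(n: int, t: ExtremesTable) -> ReductionStats:
    """Reduction statistics against an input of ``n`` points."""
    if n < 1:
        raise ValueError("n must be >= 1")
    s = len(valid_points(t))
    return ReductionStats(
        n=n,
        s=s,
        fraction_removed=(n - s) / n,
        theoretical_bound=max(0.0, 1.0 - 2.0 * t.extent / n),
    )
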