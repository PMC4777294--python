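"""Convex hull algorithms over exact integer points.

Every routine returns the same canonical form: a strictly convex,
counter-clockwise vertex ring starting at the lexicographically smallest
vertex, with collinear boundary points removed.  Degenerate inputs yield
1-vertex (all points equal) or 2-vertex (all collinear) hulls.

* :func:`melkman` — linear-time deque algorithm; requires a simple chain.
* :func:`monotone_chain` — Andrew's O(n log n) sort-based baseline.
* :func:`akl_toussaint` — the classical throw-away pre-filter: discard
  points strictly inside the quadrilateral of the four x/y extremes.
* :func:`brute_force_hull` — O(n^3) definition-driven oracle for tests.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .chain import PolygonalChain
from .reduction import Point, PointSet

__all__ = [
    "ConvexHull",
    "orientation",
    "melkman",
    "monotone_chain",
    "akl_toussaint",
    "brute_force_hull",
]


@dataclass(frozen=True)
class ConvexHull:
    """Strictly convex CCW vertex ring, lexicographically anchored."""

    vertices: tuple[Point, ...]

    @property
    def size(self) -> int:
        return len(self.vertices)

    def __iter__(self):
        return iter(self.vertices)

    def __len__(self):
        return len(self.vertices)


def orientation(a: Point, b: Point, c: Point) -> int:
    """Sign of the cross product (b - a) x (c - a); +1 is a left (CCW) turn.

    Exact integer arithmetic — never overflows, never misclassifies.
    """
    v = (b.x - a.x) * (c.y - a.y) - (b.y - a.y) * (c.x - a.x)
    return (v > 0) - (v < 0)


def _canonical(ring: list[Point]) -> ConvexHull:
    """Rotate a strictly convex CCW ring to start at the lexicographic min."""
    k = min(range(len(ring)), key=lambda i: ring[i])
    return ConvexHull(tuple(ring[k:] + ring[:k]))


def _strip_collinear(ring: list[Point]) -> list[Point]:
    """Remove collinear middles from a convex CCW ring (defensive cleanup)."""
    if len(ring) <= 2:
        return ring
    out = []
    m = len(ring)
    for i in range(m):
        a, b, c = ring[i - 1], ring[i], ring[(i + 1) % m]
        if orientation(a, b, c) > 0:
            out.append(b)
    if len(out) < 3:  # fully collinear ring
        lo, hi = min(ring), max(ring)
        return [lo] if lo == hi else [lo, hi]
    return out


def _degenerate(pts: list[Point]) -> ConvexHull | None:
    """Handle <3 distinct or fully collinear inputs; None otherwise."""
    distinct = sorted(set(pts))
    if len(distinct) == 1:
        return ConvexHull((distinct[0],))
    a, b = distinct[0], distinct[-1]
    if all(orientation(a, b, c) == 0 for c in distinct):
        return ConvexHull((a, b))
    return None


def monotone_chain(ps: PointSet | list[Point]) -> ConvexHull:
    """Andrew's monotone-chain hull with strict turns only."""
    pts = list(ps)
    if not pts:
        raise ValueError("cannot hull an empty point set")
    deg = _degenerate(pts)
    if deg is not None:
        return deg
    pts = sorted(set(pts))
    lower: list[Point] = []
    for pt in pts:
        while len(lower) >= 2 and orientation(lower[-2], lower[-1], pt) <= 0:
            lower.pop()
        lower.append(pt)
    upper: list[Point] = []
    for pt in reversed(pts):
        while len(upper) >= 2 and orientation(upper[-2], upper[-1], pt) <= 0:
            upper.pop()
        upper.append(pt)
    ring = lower[:-1] + upper[:-1]
    return _canonical(ring)


def melkman(c: PolygonalChain) -> ConvexHull:
    """Melkman's deque hull of a simple polygonal chain, in linear time.

    The deque holds the hull ring with its first and last slots equal to the
    most recently added hull vertex.  Each new chain vertex strictly inside
    the current hull is skipped in O(1); otherwise vertices are popped from
    both ends until strict convexity is restored.  A collinear prefix of the
    chain (necessarily monotone along its line, else the chain would not be
    simple) is consumed by keeping only its two endpoints.

    Raises ``ValueError`` on a chain with no vertices.
    """
    if not c.vertices:
        raise ValueError("cannot hull an empty chain")
    vs: list[Point] = [c.vertices[0]]
    for pt in c.vertices[1:]:  # collapse consecutive duplicates
        if pt != vs[-1]:
            vs.append(pt)
    deg = _degenerate(vs)
    if deg is not None:
        return deg

    # consume the leading collinear run: vs[0..k-1] lie on one line
    k = 2
    while orientation(vs[0], vs[1], vs[k]) == 0:
        k += 1
    a, b, x = vs[0], vs[k - 1], vs[k]
    if orientation(a, b, x) > 0:
        d = deque([x, a, b, x])
    else:
        d = deque([x, b, a, x])

    for pt in vs[k + 1 :]:
        if orientation(d[-2], d[-1], pt) > 0 and orientation(d[0], d[1], pt) > 0:
            continue  # strictly inside the current hull
        while len(d) > 2 and orientation(d[-2], d[-1], pt) <= 0:
            d.pop()
        d.append(pt)
        while len(d) > 2 and orientation(d[0], d[1], pt) <= 0:
            d.popleft()
        d.appendleft(pt)

    ring = _strip_collinear(list(d)[1:])  # drop duplicated anchor; ring is CCW
    if len(ring) == 1:
        return ConvexHull((ring[0],))
    if len(ring) == 2:
        lo, hi = sorted(ring)
        return ConvexHull((lo, hi))
    return _canonical(ring)


def akl_toussaint(ps: PointSet | list[Point]) -> PointSet:
    """Throw-away filter: drop points strictly inside the extreme quadrilateral.

    The four anchors are the x-min, y-min, x-max and y-max points (ties
    broken deterministically: smallest y at x-min, largest x at y-min,
    largest y at x-max, smallest x at y-max), taken in CCW order.  Points on
    the quadrilateral boundary are retained, so every hull vertex of the
    input survives.
    """
    pts = list(ps)
    if not pts:
        raise ValueError("cannot filter an empty point set")
    w = min(pts, key=lambda t: (t.x, t.y))  # x_min, smallest y
    s = min(pts, key=lambda t: (t.y, -t.x))  # y_min, largest x
    e = max(pts, key=lambda t: (t.x, t.y))  # x_max, largest y
    n = max(pts, key=lambda t: (t.y, -t.x))  # y_max, smallest x
    quad = []
    for anchor in (w, s, e, n):  # CCW with y increasing upward
        if anchor not in quad:
            quad.append(anchor)
    if len(quad) < 3:
        return PointSet(list(pts))
    edges = list(zip(quad, quad[1:] + quad[:1]))
    kept = [
        pt
        for pt in pts
        if not all(orientation(a, b, pt) > 0 for a, b in edges if a != b)
    ]
    return PointSet(kept)


def brute_force_hull(ps: PointSet | list[Point]) -> ConvexHull:
    """Definition-driven O(n^3) hull: an oracle, independent of the fast paths.

    A directed pair (a, b) is a hull edge iff every other point is strictly
    left of line ab, or collinear and strictly between a and b.  Vertices are
    then chained edge to edge.  Exact and slow; for tests only.
    """
    pts = sorted(set(ps))
    if not pts:
        raise ValueError("cannot hull an empty point set")
    deg = _degenerate(pts)
    if deg is not None:
        return deg
    nxt: dict[Point, Point] = {}
    for a in pts:
        for b in pts:
            if a == b:
                continue
            ok = True
            for cpt in pts:
                if cpt == a or cpt == b:
                    continue
                o = orientation(a, b, cpt)
                if o > 0:
                    continue
                if o == 0 and min(a.x, b.x) <= cpt.x <= max(a.x, b.x) and min(
                    a.y, b.y
                ) <= cpt.y <= max(a.y, b.y):
                    continue
                ok = False
                break
            if ok:
                nxt[a] = b
    start = min(nxt)
    ring = [start]
    cur = nxt[start]
    while cur != start:
        ring.append(cur)
        cur = nxt[cur]
    return _canonical(ring)
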