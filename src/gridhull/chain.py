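"""Simple polygonal chain construction from an extremes table.

Scanning the table in ascending order and emitting, per valid column, the
minimum point then the maximum point yields an open polyline whose edges
never intersect: within a column the edge is vertical, and consecutive
columns are bridged max-to-min with strictly increasing scan coordinate.
Such a chain is exactly the input Melkman's linear-time hull algorithm
requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .reduction import ExtremesTable, Point, _entry_points

__all__ = ["PolygonalChain", "build_chain", "is_simple"]


@dataclass
class PolygonalChain:
    """An open, ordered polyline over integer grid points."""

    vertices: list[Point] = field(default_factory=list)

    #: chains here are always open; kept explicit for clarity in exports
    closed: bool = False

    def __len__(self) -> int:
        return len(self.vertices)

    def __iter__(self):
        return iter(self.vertices)


def build_chain(t: ExtremesTable) -> PolygonalChain:
    """Connect all surviving points of ``t`` into a simple chain.

    Valid entries are visited in ascending scan coordinate; sentinel entries
    are skipped, so the bridging edge runs directly from one column's maximum
    to the next valid column's minimum.  Within a column the minimum always
    precedes the maximum.

    Raises ``ValueError`` when the table holds no valid entry.
    """
    verts = list(_entry_points(t))
    if not verts:
        raise ValueError("empty reduction: table has no valid entries")
    return PolygonalChain(verts)


def _sign(v: int) -> int:
    return (v > 0) - (v < 0)


def _orient(a: Point, b: Point, c: Point) -> int:
    return _sign((b.x - a.x) * (c.y - a.y) - (b.y - a.y) * (c.x - a.x))


def _on_segment(a: Point, b: Point, c: Point) -> bool:
    """True iff collinear point c lies on closed segment ab."""
    return min(a.x, b.x) <= c.x <= max(a.x, b.x) and min(a.y, b.y) <= c.y <= max(a.y, b.y)


def _segments_touch(p1: Point, p2: Point, p3: Point, p4: Point) -> bool:
    """Exact test: do closed segments p1p2 and p3p4 share any point?"""
    d1 = _orient(p3, p4, p1)
    d2 = _orient(p3, p4, p2)
    d3 = _orient(p1, p2, p3)
    d4 = _orient(p1, p2, p4)
    if ((d1 > 0 and d2 < 0) or (d1 < 0 and d2 > 0)) and (
        (d3 > 0 and d4 < 0) or (d3 < 0 and d4 > 0)
    ):
        return True
    if d1 == 0 and _on_segment(p3, p4, p1):
        return True
    if d2 == 0 and _on_segment(p3, p4, p2):
        return True
    if d3 == 0 and _on_segment(p1, p2, p3):
        return True
    if d4 == 0 and _on_segment(p1, p2, p4):
        return True
    return False


def is_simple(c: PolygonalChain) -> bool:
    """Exhaustive O(m^2) simplicity check in exact integer arithmetic.

    True iff non-adjacent edges share no point and adjacent edges meet only
    at their common vertex.  Intended as a test oracle; the production path
    trusts the chain construction.
    """
    vs = c.vertices
    if len(vs) <= 2:
        return True
    edges = list(zip(vs, vs[1:]))
    for i in range(len(edges)):
        a, b = edges[i]
        if a == b:
            return False
        for j in range(i + 1, len(edges)):
            p, q = edges[j]
            if j == i + 1:
                # share vertex b == p; any further contact requires the two
                # edges to be collinear and fold back over each other
                if _orient(a, b, q) == 0 and (a.x - b.x) * (q.x - b.x) + (
                    a.y - b.y
                ) * (q.y - b.y) > 0:
                    return False
            elif _segments_touch(a, b, p, q):
                return False
    return True
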