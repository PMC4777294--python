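"""Shared fixtures and randomized-instance builders for the test suite."""

import random

import pytest

from gridhull.reduction import ExtremesTable, Point, PointSet, valid_points

# The worked example: a 5x5 grid whose per-column (min, max) table is
# [(1,4),(2,4),(2,5),(3,3),(2,3)].  Expanding the table yields nine points
# whose strict convex hull is a pentagon.
PRINTED_ENTRIES = [(1, 4), (2, 4), (2, 5), (3, 3), (2, 3)]
PENTAGON = (Point(1, 1), Point(5, 2), Point(5, 3), Point(3, 5), Point(1, 4))


@pytest.fixture
def printed_table() -> ExtremesTable:
    return ExtremesTable("x", 1, 1, 5, list(PRINTED_ENTRIES))


@pytest.fixture
def nine_points(printed_table) -> PointSet:
    return valid_points(printed_table)


def make_pointset(rng: random.Random, n: int, p: int, q: int) -> PointSet:
    """n uniform lattice points in [1..p] x [1..q], duplicates allowed."""
    return PointSet([Point(rng.randint(1, p), rng.randint(1, q)) for _ in range(n)])


def make_degenerate_pointset(rng: random.Random) -> PointSet:
    """Adversarial small sets: single columns, collinear runs, n < 3, dupes."""
    kind = rng.randrange(5)
    if kind == 0:  # single column
        x = rng.randint(1, 10)
        return PointSet([Point(x, rng.randint(1, 20)) for _ in range(rng.randint(1, 12))])
    if kind == 1:  # collinear along a random line through the origin
        dx, dy = rng.randint(0, 3), rng.randint(0, 3)
        if dx == dy == 0:
            dx = 1
        return PointSet(
            [Point(1 + k * dx, 1 + k * dy) for k in rng.choices(range(8), k=rng.randint(1, 10))]
        )
    if kind == 2:  # n < 3
        return make_pointset(rng, rng.randint(1, 2), 6, 6)
    if kind == 3:  # heavy duplication
        base = make_pointset(rng, rng.randint(1, 4), 8, 8)
        return PointSet(rng.choices(list(base), k=rng.randint(4, 15)))
    return make_pointset(rng, rng.randint(3, 25), rng.randint(1, 12), rng.randint(1, 12))


def make_table(rng: random.Random) -> ExtremesTable:
    """A random valid extremes table with at least one non-sentinel entry."""
    extent = rng.randint(1, 15)
    cross_extent = rng.randint(1, 15)
    origin = rng.randint(-5, 5)
    cross_origin = rng.randint(-5, 5)
    sentinel = (cross_extent + 1, -1)
    entries = []
    for _ in range(extent):
        if rng.random() < 0.3:
            entries.append(sentinel)
        else:
            u = rng.randint(1, cross_extent)
            v = rng.randint(u, cross_extent)
            entries.append((u, v))
    if all(e == sentinel for e in entries):
        entries[rng.randrange(extent)] = (1, cross_extent)
    return ExtremesTable(rng.choice(["x", "y"]), origin, cross_origin, cross_extent, entries)
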