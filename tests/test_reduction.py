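"""Unit tests for bounding boxes, the decision rule, and the reduction."""

import random

import pytest

from conftest import PRINTED_ENTRIES, make_pointset
from gridhull.reduction import (
    BoundingBox,
    ExtremesTable,
    Point,
    PointSet,
    compute_bounding_box,
    decide,
    reduce,
    stats,
    valid_points,
)


class TestBoundingBox:
    def test_worked_example_box(self, nine_points):
        bbox = compute_bounding_box(nine_points)
        assert (bbox.p, bbox.q, bbox.m) == (5, 5, 25)
        assert (bbox.x_min, bbox.x_max, bbox.y_min, bbox.y_max) == (1, 5, 1, 5)

    def test_single_point_degenerate_box(self):
        bbox = compute_bounding_box(PointSet([Point(3, 7)]))
        assert (bbox.p, bbox.q, bbox.m) == (1, 1, 1)

    def test_matches_linear_scan_oracle(self):
        rng = random.Random(7)
        ps = make_pointset(rng, 500, 200, 90)
        xs = sorted(pt.x for pt in ps)
        ys = sorted(pt.y for pt in ps)
        bbox = compute_bounding_box(ps)
        assert (bbox.x_min, bbox.x_max) == (xs[0], xs[-1])
        assert (bbox.y_min, bbox.y_max) == (ys[0], ys[-1])

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            compute_bounding_box(PointSet([]))

    def test_inverted_box_is_an_error(self):
        with pytest.raises(ValueError):
            BoundingBox(5, 1, 0, 0)


class TestDecide:
    @pytest.mark.parametrize(
        "p, q, n, mode",
        [
            (5, 5, 9, "apply_along_x"),  # worked example: p <= q, p <= n
            (10**6, 10**6, 120_000, "skip"),  # sparse UTM-scale extents
            (1, 1, 1, "apply_along_x"),  # boundary equality min(p,q) == n
            (50, 10, 30, "apply_along_y"),  # q < p scans along y
            (7, 7, 7, "apply_along_x"),  # p == q tie resolves to x
            (3, 1000, 2, "skip"),  # min(p,q) just above n
        ],
    )
    def test_decision_rule(self, p, q, n, mode):
        bbox = BoundingBox(1, p, 1, q)
        decision = decide(bbox, n)
        assert decision.mode == mode
        assert (decision.axis is None) == (mode == "skip")

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            decide(BoundingBox(1, 5, 1, 5), 0)


class TestReduce:
    def test_reproduces_printed_table_in_any_order(self, nine_points, printed_table):
        rng = random.Random(0)
        pts = list(nine_points)
        for _ in range(10):
            rng.shuffle(pts)
            t = reduce(PointSet(pts), compute_bounding_box(nine_points), "x")
            assert t.entries == PRINTED_ENTRIES
            assert (t.origin, t.cross_origin, t.cross_extent) == (1, 1, 5)
            assert t.sentinel == (6, -1)

    def test_single_column_with_sentinel(self):
        # box forced wider than the data: column 1 stays at the sentinel
        ps = PointSet([Point(2, 9), Point(2, 1), Point(2, 5)])
        t = reduce(ps, BoundingBox(1, 2, 1, 9), "x")
        assert t.entries == [(10, -1), (1, 9)]

    def test_matches_groupby_oracle(self):
        rng = random.Random(11)
        ps = make_pointset(rng, 1000, 50, 50)
        bbox = compute_bounding_box(ps)
        t = reduce(ps, bbox, "x")
        by_col: dict[int, list[int]] = {}
        for pt in ps:
            by_col.setdefault(pt.x, []).append(pt.y)
        for i, (u, v) in enumerate(t.entries):
            col = bbox.x_min + i
            if col in by_col:
                assert (u, v) == (
                    min(by_col[col]) - bbox.y_min + 1,
                    max(by_col[col]) - bbox.y_min + 1,
                )
            else:
                assert (u, v) == t.sentinel

    def test_y_axis_scan_transposes(self):
        ps = PointSet([Point(1, 2), Point(9, 2), Point(4, 2)])
        t = reduce(ps, compute_bounding_box(ps), "y")
        assert t.axis == "y"
        assert t.entries == [(1, 9)]
        assert [tuple(p) for p in valid_points(t)] == [(1, 2), (9, 2)]

    def test_point_outside_box_is_an_error(self):
        ps = PointSet([Point(1, 1), Point(4, 4)])
        with pytest.raises(ValueError, match="outside"):
            reduce(ps, BoundingBox(1, 3, 1, 3), "x")

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            reduce(PointSet([]), BoundingBox(1, 1, 1, 1), "x")

    def test_each_point_visited_exactly_once(self, nine_points):
        seen = []

        class CountingPointSet(PointSet):
            def __iter__(self):
                for pt in self.points:
                    seen.append(pt)
                    yield pt

        counted = CountingPointSet(list(nine_points))
        reduce(counted, compute_bounding_box(nine_points), "x")
        assert len(seen) == len(nine_points)


class TestValidPoints:
    def test_printed_table_expands_to_nine(self, printed_table):
        pts = valid_points(printed_table)
        # column 4 has u == v == 3 and contributes a single point
        assert pts.n == 9
        assert sum(1 for p in pts if p.x == 4) == 1

    def test_all_sentinel_table_is_empty(self):
        t = ExtremesTable("x", 1, 1, 5, [(6, -1)] * 3)
        assert valid_points(t).n == 0

    def test_count_matches_entry_census(self):
        rng = random.Random(3)
        from conftest import make_table

        for _ in range(50):
            t = make_table(rng)
            singles = sum(
                1 for e in t.entries if e != t.sentinel and e[0] == e[1]
            )
            doubles = sum(
                1 for e in t.entries if e != t.sentinel and e[0] != e[1]
            )
            assert valid_points(t).n == singles + 2 * doubles


class TestStats:
    def test_worked_example_removes_nothing(self, nine_points, printed_table):
        st = stats(nine_points.n, printed_table)
        assert st.s == 9
        assert st.fraction_removed == 0.0

    def test_constructed_worst_case_meets_bound(self):
        # every column holds >= 2 distinct values: exactly 2 per column survive
        pts = PointSet(
            [Point(i, y) for i in range(1, 101) for y in (1, 3, 5, 7, 9)]
        )
        t = reduce(pts, compute_bounding_box(pts), "x")
        st = stats(pts.n, t)
        assert st.s == 200
        assert st.fraction_removed == pytest.approx(0.6)
        assert st.theoretical_bound == pytest.approx(0.6)
        assert st.fraction_removed >= st.theoretical_bound

    def test_bound_clamped_at_zero(self, printed_table):
        st = stats(9, printed_table)
        assert st.theoretical_bound == 0.0
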