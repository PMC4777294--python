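"""The small grid example: reduce nine points on a 5x5 grid to a pentagon.

Builds the nine-point set whose per-column (min, max) extremes table is
[(1,4), (2,4), (2,5), (3,3), (2,3)], runs the one-pass reduction, connects
the survivors into a simple polygonal chain, and hulls the chain with
Melkman's linear-time algorithm.
"""

import gridhull as gh

table = gh.ExtremesTable("x", origin=1, cross_origin=1, cross_extent=5,
                         entries=[(1, 4), (2, 4), (2, 5), (3, 3), (2, 3)])
points = gh.valid_points(table)
print("input points :", [tuple(p) for p in points])

bbox = gh.compute_bounding_box(points)
decision = gh.decide(bbox, points.n)
print(f"box          : p={bbox.p} q={bbox.q}  ->  {decision.mode}")

reduced = gh.reduce(points, bbox, "x")
print("extremes L   :", reduced.entries, " (sentinel", reduced.sentinel, ")")

chain = gh.build_chain(reduced)
print("chain        :", [tuple(v) for v in chain], "simple:", gh.is_simple(chain))

hull = gh.melkman(chain)
print("hull         :", [tuple(v) for v in hull])
print(f"-> the {hull.size}-vertex strict hull (a pentagon); the reduction kept")
print("   all nine points here because the example is already its own reduction.")
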