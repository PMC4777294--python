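"""Sparse scatter (homerange-style): the decision rule says skip.

Animal-movement fixes in UTM-like coordinates span boxes of ~10^6 units
on a side while recording only a few hundred positions, so min(p, q) > n:
the reduction would cost O(n + p), remove almost nothing, and is skipped.
The minimum convex polygon (the ecology homerange estimate) is then
computed directly on the raw fixes — preconditioning never changes it.
"""

import gridhull as gh

fixes = gh.generate(gh.ShapeSpec("sparse_box", n=300, p=10**6, q=10**6, seed=3))
bbox = gh.compute_bounding_box(fixes)
result = gh.run(fixes, "monotone_chain")

print(f"n = {fixes.n} fixes in a {bbox.p} x {bbox.q} box")
print(f"decision: {result.decision.mode}  ({result.decision.reason})")
print(f"minimum convex polygon has {result.hull.size} vertices")

forced = gh.run(fixes, "melkman", force_precondition=True)
print("forcing the reduction anyway gives the same hull:", forced.hull == result.hull)
print(f"  (but keeps s = {forced.stats.s} of {fixes.n} points — no point in it)")
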