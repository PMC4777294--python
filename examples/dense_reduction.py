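"""Dense data: how much does the one-pass reduction remove?

40,000 uniform lattice points in a 1000 x 1000 box leave at most two
survivors per column (s <= 2p = 2000), i.e. removal of at least
1 - 2p/n = 95%.  The hull of the survivors is identical to the hull of
the full input.
"""

import gridhull as gh

ps = gh.generate(gh.ShapeSpec("dense_box", n=40_000, p=1000, q=1000, seed=42))
bbox = gh.compute_bounding_box(ps)
table = gh.reduce(ps, bbox, "x")
st = gh.stats(ps.n, table)

print(f"n = {st.n}, surviving s = {st.s}")
print(f"removed {100 * st.fraction_removed:.2f}%  (analytic bound {100 * st.theoretical_bound:.2f}%)")

hull_reduced = gh.melkman(gh.build_chain(table))
hull_direct = gh.monotone_chain(ps)
print("hull unchanged by the reduction:", hull_reduced == hull_direct,
      f"({hull_reduced.size} vertices)")
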