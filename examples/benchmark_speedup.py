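"""Benchmark the preconditioned hull against the direct computation.

Times three phases on a dense synthetic disc: t_n (direct hull on all n
points), t_r (the one-pass reduction), t_s (survivor extraction, chain and
hull on the reduced set), and reports the speedup t_n / (t_r + t_s).
Timings are hardware-dependent; the counts are exact.
"""

import gridhull as gh

ps = gh.generate(gh.ShapeSpec("disc", n=100_000, p=800, q=800, seed=11))
rec = gh.benchmark(ps, algorithm="melkman", repeats=5)

print(f"n = {rec.n}, box {rec.p} x {rec.q}, sparsity min(p,q)/n = {rec.sparsity:.4f}")
print(f"s = {rec.s} survivors, {100 * rec.fraction_removed:.2f}% removed")
print(f"t_n = {rec.t_n * 1e3:.2f} ms   t_r = {rec.t_r * 1e3:.2f} ms   t_s = {rec.t_s * 1e3:.2f} ms")
print(f"speedup t_n / (t_r + t_s) = {rec.speedup:.2f}")
print("-> the smaller min(p,q)/n is, the larger the speedup; counts are")
print("   deterministic, timings vary run to run.")
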