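# Methods

## Model and assumptions

The package operates on finite multisets of 2D points with exact integer
coordinates, bounded by an axis-aligned box with inclusive side lengths
`p = x_max − x_min + 1` and `q = y_max − y_min + 1` (lattice counts, not
geometric lengths). The central primitive is a one-pass reduction: scanning
the points once while maintaining, per column of the smaller box side, the
minimum and maximum of the other coordinate. Because a convex hull vertex
must be extremal in its column, the survivors — at most two per column,
`s ≤ 2·extent` — carry the same strict convex hull as the input. Duplicates
and input order are irrelevant to the result (min/max updates are
idempotent and commutative), which the suite asserts as order-invariance
and idempotence properties.

The reduction is applied only when `min(p, q) ≤ n`. Above that threshold
the extremes table would have more entries than there are points: the pass
degrades to `O(n + p)`, removes little, and for UTM-scale extents
(`p ~ 10^6`) would allocate a table far larger than the data. The skip path
therefore allocates nothing and hulls the raw points; a `force_precondition`
flag exists because correctness is unaffected either way, only speed.

Survivors are emitted in ascending column order, minimum before maximum
within a column. Connecting them in that order yields an open polyline
whose edges cannot intersect: within-column edges are vertical, bridging
edges strictly advance the scan coordinate. Any collinear stretch of a
simple chain is necessarily monotone along its line (overlapping collinear
edges would intersect), which is what lets the Melkman implementation
collapse a collinear prefix to its two endpoints before seeding the deque.

## Coordinate conventions

Inputs are translated so the scan coordinate is 1-based over `[1..extent]`
and the cross coordinate over `[1..cross_extent]`; the offsets ride on the
`ExtremesTable` and are inverted when survivors are read out. The sentinel
for an untouched column is the literal pair `(cross_extent + 1, −1)` in
translated coordinates — the initialization value whose min/max updates are
identities — so serialized tables are directly comparable against
hand-computed ones. When `p = q` the scan runs along x (deterministic
tie-break).

Image rasters map pixel `(column c, row r)` (0-based, row 0 at the top) to
point `(c + 1, height − r)`: 1-based, y up. The mapping is a bijection on
foreground pixels and is fixed package-wide because hull vertex coordinates
depend on it. Pixel anisotropy is out of scope; hulls are computed in pixel
units.

## Hull algorithms and canonical form

All hull routines return the same canonical object: a strictly convex CCW
ring (collinear boundary points removed) starting at the lexicographically
smallest vertex; 1-vertex and 2-vertex degenerate hulls are legal outputs.
Fixing strict convexity everywhere makes vertex-ring comparisons exact
across algorithms; external libraries may keep collinear vertices, so the
cross-library test strips them from qhull's ring before comparing.

* **Melkman** (deque, `O(n)` on a simple chain): strict-turn popping with
  deque-length guards plus a final collinear-strip pass as a defensive
  cleanup; points on the current hull boundary are treated as outside so
  collinear vertices never accumulate.
* **Monotone chain** (Andrew's `O(n log n)`, strict turns): the sort-based
  baseline standing in for library hull implementations.
* **Akl–Toussaint filter**: discards points strictly inside the
  quadrilateral of the four x/y extremes. Tie-breaks (the classical
  formulation leaves them open) are fixed as: smallest y at x-min, largest
  x at y-min, largest y at x-max, smallest x at y-max; boundary points are
  retained — the safe side, no hull vertex can be lost.
* **Brute force** (`O(n^3)`): a directed pair `(a, b)` is a hull edge iff
  every other point is strictly left of it or collinear strictly between
  its endpoints. Definition-driven and independent of the fast paths; the
  primary test oracle.

The orientation predicate is an exact integer cross-product sign, so no
tolerance or robustness machinery exists anywhere in the geometry.

## Synthetic data

The generators emulate the four regimes the method targets, and their
defaults are the study conditions used throughout the tests:

* `disc` / `superellipse` — `n` lattice points uniform (with replacement)
  in `|2(x−c_x)/p|^e + |2(y−c_y)/q|^e ≤ 1` inscribed in the box; `e = 2`
  (circle/ellipse) is the disc default, `e = 4` the superellipse default.
  Membership is evaluated exactly for any positive integer exponent by
  clearing denominators (`|2x−p−1|^e q^e + |2y−q−1|^e p^e ≤ (pq)^e`);
  non-integer exponents fall back to float evaluation and are therefore not
  bit-reproducible across platforms in principle (they are on any IEEE-754
  machine).
* `dense_box` — `n` uniform lattice points with `p ≪ n` (defaults used in
  acceptance: `n = 40,000` in a `1000 × 1000` box, the `p/n = 1/40` regime
  where the removal bound is 95%).
* `sparse_box` — the same sampler in a huge box (`min(p, q) > n`),
  emulating homerange-style UTM scatters that trigger the skip rule.
* `mask` — the full lattice rasterization of the superellipse region as a
  binary image (`exponent = inf` fills the box), emulating segmented image
  planes.

Sampling is with replacement so `n` is exact and duplicates occur, as they
do in real pixel data; the reduction is insensitive to them. What these
generators do **not** emulate: correlated/clustered spatial structure,
holes and concavities of real segmentations, and heavy-tailed movement
data. Passing tests therefore demonstrate correctness and the counting
behavior of the method, not its speedup on any particular real dataset —
timings are reported by the benchmark harness but never asserted.

## Benchmarking

`benchmark()` times three phases with a monotonic clock, garbage collection
paused, median over `repeats` (default 5): `t_n` the direct hull on all
points, `t_r` bounding box + decision + reduction (translation is part of
the reduction cost), `t_s` survivor extraction + chain + hull. The speedup
statistic is `t_n / (t_r + t_s)`. Counts (`n`, `s`, fraction removed,
sparsity `min(p,q)/n`) are deterministic; serialized records carry exactly
the ten documented keys, and aggregation across datasets is left to the
user. The direct-hull baseline is the monotone chain (Melkman cannot run on
unordered raw points), so reported speedups compare a linear preconditioned
path against an `O(n log n)` baseline of the same code quality.

## Numerical and design choices

* `n = 0` is a hard error in every entry point; `n < 3` is reduced normally
  and handled as a degenerate hull downstream.
* The simplicity checker (`O(m^2)`, exact) is a test oracle; the production
  path relies on the constructive simplicity of the chain.
* Problem sizes in the tests are chosen to keep the `O(n^3)` oracle
  comfortable: randomized hull-preservation instances use up to ~30 points
  over boxes up to 15×15, with dedicated dense runs at `n = 40,000` where
  only counting (not the cubic oracle) is asserted.
* Random point generation uses `numpy`'s PCG64 generator; a spec plus seed
  is bit-reproducible.

## Known limitations

Integer coordinates only (rational or float inputs must be scaled and
snapped by the caller, which changes the geometry); 2D only; the extremes
table is dense over the scan extent, so forcing the reduction on sparse
data with huge extents costs memory proportional to the extent; PGM is the
only guaranteed image format (maxval ≤ 255).
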