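# gridhull

Linear-time preconditioning of 2D integer point sets for fast convex hull
computation.

Many datasets whose convex hull is wanted are integer-valued by nature:
foreground pixels of a segmented binary image, dense planar projections of
3D point clouds, animal-movement fixes snapped to a metre grid (the
minimum convex polygon of ecology). For `n` such points bounded by a
`p × q` box, a single unsorted pass can discard almost all of them before
any hull algorithm runs, while provably preserving the hull.

## The method

Write the points as `(x, y)` with `x ∈ [1..p]`, `y ∈ [1..q]`, `p ≤ q`
(otherwise swap the roles of the axes). One pass over the input maintains
an array `L` of `p` entries, each initialized to the sentinel `(q+1, −1)`;
for every point, entry `L[x]` is updated to `(min(y, u), max(y, v))`. Only
the per-column extremes can be hull vertices, so the survivors number at
most `s = 2p`, a removal fraction of at least `1 − 2p/n` when every column
is populated. Three properties make this preconditioner attractive:

* under the condition `min(p, q) ≤ n` it runs in `O(n)` time;
* no sorting is involved, unlike the classical throw-away heuristic of
  Akl and Toussaint;
* read out in column order (min then max), the survivors form a **simple
  polygonal chain**, exactly the input Melkman's `O(n)` deque hull
  algorithm requires — so the whole hull computation is linear.

When `min(p, q) > n` (sparse scatters in huge boxes) the pass would cost
`O(n + p)` and remove little, so the decision rule skips it and hulls the
raw points directly; correctness never depends on the decision.

All core arithmetic is exact integer arithmetic; hulls are returned as
strictly convex counter-clockwise rings (collinear boundary points
removed) anchored at the lexicographically smallest vertex.

## Worked example

The canonical small example — nine points on a 5 × 5 grid
(`python examples/worked_example.py`):

```
input points : [(1, 1), (1, 4), (2, 2), (2, 4), (3, 2), (3, 5), (4, 3), (5, 2), (5, 3)]
box          : p=5 q=5  ->  apply_along_x
extremes L   : [(1, 4), (2, 4), (2, 5), (3, 3), (2, 3)]  (sentinel (6, -1) )
chain        : [(1, 1), (1, 4), (2, 2), (2, 4), (3, 2), (3, 5), (4, 3), (5, 2), (5, 3)] simple: True
hull         : [(1, 1), (5, 2), (5, 3), (3, 5), (1, 4)]
```

Entry `L[1] = (1, 4)` records that column `x = 1` spans `y = 1..4`; the
chain visits each column's minimum then maximum; Melkman's algorithm turns
the chain into the 5-vertex strict hull (a pentagon). At scale the effect
is dramatic (`python examples/dense_reduction.py`):

```
n = 40000, surviving s = 2000
removed 95.00%  (analytic bound 95.00%)
hull unchanged by the reduction: True (13 vertices)
```

Other example scripts cover binary-image masks (`image_mask_hull.py`),
sparse homerange data and the skip rule (`sparse_homerange.py`), and phase
timings with the speedup statistic `t_n / (t_r + t_s)`
(`benchmark_speedup.py`).

## Command line

A thin CLI wraps the library:

```
gridhull generate --kind disc --n 5000 --p 400 --q 300 --seed 1 --out pts.csv
gridhull reduce   --in pts.csv --out reduced.csv --table table.csv
gridhull hull     --in pts.csv --algorithm melkman --out hull.csv --wkt hull.wkt
gridhull bench    --in pts.csv --algorithm monotone --repeats 5 --out record.json
```

Point files are two-column integer CSV/TSV (optional `x,y` header); binary
images are PGM (P2/P5), with pixel `(column c, row r)` mapped to point
`(c+1, height−r)`.

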