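"""Synthetic datasets emulating the study conditions.

Four families, mirroring the kinds of data the preconditioning method is
aimed at:

* ``disc`` / ``superellipse`` — n random lattice points inside a filled
  region inscribed in a p x q box (image-object-like blobs; exponent e = 2
  gives a circle/ellipse, larger e boxier shapes).
* ``dense_box`` — n uniform lattice points in the box with p << n (dense
  projections; nearly every column survives with exactly two points).
* ``sparse_box`` — n uniform lattice points in a huge box, min(p, q) > n
  (homerange-style UTM scatters; the decision rule skips these).
* ``mask`` — a p x q binary raster whose foreground is the filled region
  itself (segmented-image analogue).

Region membership is evaluated in exact integer arithmetic for any positive
integer exponent; generation is reproducible from the seed alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io import ImageRaster
from .reduction import Point, PointSet

__all__ = ["ShapeSpec", "generate", "generate_mask"]

Kind = Literal["disc", "superellipse", "dense_box", "sparse_box", "mask"]

#: default superellipse exponents per kind (circle is e = 2)
_DEFAULT_EXPONENT = {"disc": 2.0, "superellipse": 4.0, "mask": 2.0}


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of one synthetic dataset.

    ``n`` is the exact number of points emitted (sampling is with
    replacement, so duplicates can occur — the reduction is insensitive to
    them).  ``p`` and ``q`` are the box sides in lattice units; coordinates
    lie in [1..p] x [1..q].  ``exponent`` only matters for the region kinds;
    ``math.inf`` means the full box.
    """

    kind: Kind
    n: int
    p: int
    q: int
    exponent: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("disc", "superellipse", "dense_box", "sparse_box", "mask"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.p < 1 or self.q < 1:
            raise ValueError("box sides must be >= 1")
        if self.exponent is not None and not self.exponent > 0:
            raise ValueError("exponent must be > 0")

    @property
    def e(self) -> float:
        if self.exponent is not None:
            return self.exponent
        return _DEFAULT_EXPONENT.get(self.kind, 2.0)


def _member(x: int, y: int, p: int, q: int, e: float) -> bool:
    """Is lattice point (x, y) inside |2(x-cx)/p|^e + |2(y-cy)/q|^e <= 1?

    The box center is ((p+1)/2, (q+1)/2); writing X = 2x - p - 1 and
    Y = 2y - q - 1 clears the halves, and for integer e the test becomes
    |X|^e q^e + |Y|^e p^e <= (pq)^e in exact integer arithmetic.  Non-integer
    exponents fall back to float evaluation.
    """
    X = abs(2 * x - p - 1)
    Y = abs(2 * y - q - 1)
    if math.isinf(e):
        return X <= p and Y <= q
    if float(e).is_integer():
        k = int(e)
        return X**k * q**k + Y**k * p**k <= (p * q) ** k
    return (X / p) ** e + (Y / q) ** e <= 1.0


def generate(spec: ShapeSpec) -> PointSet:
    """Draw exactly ``spec.n`` lattice points for the given dataset family.

    Region kinds use rejection sampling from the box (uniform over member
    lattice points, with replacement); box kinds sample the box directly.
    Identical specs produce bit-identical point sets.

    Raises ``ValueError`` if the region contains no lattice point.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind in ("dense_box", "sparse_box"):
        xs = rng.integers(1, spec.p + 1, size=spec.n)
        ys = rng.integers(1, spec.q + 1, size=spec.n)
        return PointSet([Point(int(x), int(y)) for x, y in zip(xs, ys)])
    if spec.kind == "mask":
        raise ValueError("kind='mask' generates a raster; use generate_mask")

    p, q, e = spec.p, spec.q, spec.e
    pts: list[Point] = []
    empty_batches = 0
    while len(pts) < spec.n:
        batch = max(1024, 2 * (spec.n - len(pts)))
        xs = rng.integers(1, p + 1, size=batch)
        ys = rng.integers(1, q + 1, size=batch)
        found = False
        for x, y in zip(xs, ys):
            if _member(int(x), int(y), p, q, e):
                pts.append(Point(int(x), int(y)))
                found = True
                if len(pts) == spec.n:
                    break
        if not found:
            empty_batches += 1
            # a filled superellipse covers a constant fraction of its box;
            # repeated all-miss batches mean the region has no lattice point
            if empty_batches >= 8 and not _region_has_lattice_point(p, q, e):
                raise ValueError(
                    f"region kind={spec.kind!r} e={e} in {p} x {q} box "
                    "contains no lattice point"
                )
    return PointSet(pts)


def _region_has_lattice_point(p: int, q: int, e: float) -> bool:
    return any(
        _member(x, y, p, q, e) for x in range(1, p + 1) for y in range(1, q + 1)
    )


def generate_mask(spec: ShapeSpec) -> ImageRaster:
    """Rasterize the spec's region as a p x q binary image.

    Foreground pixels are exactly the member lattice points under the io
    module's pixel-to-point convention, so reading the mask back yields the
    region's full lattice set.  ``exponent=math.inf`` fills the whole box.

    Raises ``ValueError`` when the foreground would be empty.
    """
    if spec.kind != "mask":
        raise ValueError(f"generate_mask requires kind='mask', got {spec.kind!r}")
    p, q, e = spec.p, spec.q, spec.e
    grid = np.zeros((q, p), dtype=np.uint8)
    count = 0
    for x in range(1, p + 1):
        for y in range(1, q + 1):
            if _member(x, y, p, q, e):
                grid[q - y, x - 1] = 1
                count += 1
    if count == 0:
        raise ValueError(f"mask e={e} in {p} x {q} box has empty foreground")
    return ImageRaster(p, q, grid)
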