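"""Readers and writers: point CSV/TSV, PGM images, hull CSV/WKT.

Pixel-to-point convention (fixed here, documented because hull vertex
coordinates depend on it): pixel at column ``c`` (0-based, left to right)
and row ``r`` (0-based, top to bottom) maps to point ``(c + 1, height - r)``
— 1-based grid coordinates with y increasing upward.  The mapping is a
bijection between foreground pixels and points.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .hulls import ConvexHull
from .reduction import ExtremesTable, Point, PointSet

__all__ = [
    "ImageRaster",
    "read_points",
    "write_points",
    "image_to_points",
    "points_to_image",
    "read_pgm",
    "write_pgm",
    "write_hull_csv",
    "read_hull_csv",
    "hull_to_wkt",
    "write_hull_wkt",
    "write_extremes_table",
    "write_chain_csv",
]


@dataclass
class ImageRaster:
    """A grayscale raster; values > 0 are foreground by default downstream."""

    width: int
    height: int
    pixels: np.ndarray  # shape (height, width), dtype uint8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.shape != (self.height, self.width):
            raise ValueError(
                f"pixel grid {self.pixels.shape} does not match "
                f"{self.height} x {self.width}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImageRaster):
            return NotImplemented
        return (
            self.width == other.width
            and self.height == other.height
            and bool(np.array_equal(self.pixels, other.pixels))
        )


def read_points(path: str | Path, dialect: Literal["csv", "tsv"] | None = None) -> PointSet:
    """Read a two-column integer point file; optional ``x,y`` header.

    The dialect defaults from the file extension (``.tsv`` means tabs).
    Malformed rows raise ``ValueError`` naming the offending line number.
    """
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() == ".tsv" else "csv"
    delim = "\t" if dialect == "tsv" else ","
    pts: list[Point] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delim), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and [c.strip().lower() for c in row] == ["x", "y"]:
                continue
            if len(row) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(row)}")
            try:
                pts.append(Point(int(row[0]), int(row[1])))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer cell in row {row!r}"
                ) from None
    if not pts:
        raise ValueError(f"{path}: no points found")
    return PointSet(pts)


def write_points(ps: PointSet, path: str | Path, dialect: Literal["csv", "tsv"] = "csv") -> None:
    delim = "\t" if dialect == "tsv" else ","
    with open(path, "w", newline="") as fh:
        fh.write(f"x{delim}y\n")
        for pt in ps:
            fh.write(f"{pt.x}{delim}{pt.y}\n")


def image_to_points(
    img: ImageRaster, foreground: Literal["nonzero", "zero"] = "nonzero"
) -> PointSet:
    """One point per foreground pixel, per the module's fixed convention."""
    mask = img.pixels != 0 if foreground == "nonzero" else img.pixels == 0
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("image has no foreground pixels")
    # points in raster scan order (top row first, left to right)
    return PointSet(
        [Point(int(col) + 1, img.height - int(row)) for row, col in zip(rows, cols)]
    )


def points_to_image(ps: PointSet, width: int, height: int) -> ImageRaster:
    """Inverse of :func:`image_to_points` onto a given canvas."""
    grid = np.zeros((height, width), dtype=np.uint8)
    for pt in ps:
        if not (1 <= pt.x <= width and 1 <= pt.y <= height):
            raise ValueError(f"point {tuple(pt)} outside {width} x {height} canvas")
        grid[height - pt.y, pt.x - 1] = 1
    return ImageRaster(width, height, grid)


def _pgm_tokens(data: bytes):
    """Token stream over a PGM header, skipping '#' comments."""
    i = 0
    while i < len(data):
        ch = data[i : i + 1]
        if ch.isspace():
            i += 1
        elif ch == b"#":
            while i < len(data) and data[i : i + 1] != b"\n":
                i += 1
        else:
            j = i
            while j < len(data) and not data[j : j + 1].isspace():
                j += 1
            yield data[i:j], j
            i = j


def read_pgm(path: str | Path) -> ImageRaster:
    """Read a P2 (ASCII) or P5 (binary) PGM with maxval <= 255."""
    data = Path(path).read_bytes()
    tokens = _pgm_tokens(data)
    try:
        magic, _ = next(tokens)
        if magic not in (b"P2", b"P5"):
            raise ValueError(f"{path}: not a P2/P5 PGM (magic {magic!r})")
        (w_tok, _), (h_tok, _), (max_tok, end) = next(tokens), next(tokens), next(tokens)
        width, height, maxval = int(w_tok), int(h_tok), int(max_tok)
    except (StopIteration, ValueError) as exc:
        raise ValueError(f"{path}: malformed PGM header") from exc
    if width < 1 or height < 1:
        raise ValueError(f"{path}: bad dimensions {width} x {height}")
    if not 0 < maxval <= 255:
        raise ValueError(f"{path}: unsupported maxval {maxval}")
    count = width * height
    if magic == b"P5":
        raw = data[end + 1 : end + 1 + count]  # single whitespace after maxval
        if len(raw) < count:
            raise ValueError(f"{path}: truncated P5 pixel data")
        grid = np.frombuffer(raw, dtype=np.uint8, count=count)
    else:
        values = data[end:].split()
        if len(values) < count:
            raise ValueError(f"{path}: truncated P2 pixel data")
        grid = np.array([int(v) for v in values[:count]], dtype=np.uint8)
    return ImageRaster(width, height, grid.reshape(height, width))


def write_pgm(img: ImageRaster, path: str | Path, binary: bool = False) -> None:
    """Write PGM; ASCII P2 by default (text-friendly), P5 when ``binary``."""
    maxval = max(1, int(img.pixels.max()))
    header = f"{'P5' if binary else 'P2'}\n{img.width} {img.height}\n{maxval}\n"
    if binary:
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(img.pixels.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write(header)
            for row in img.pixels:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")


def write_hull_csv(hull: ConvexHull, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("x,y\n")
        for pt in hull:
            fh.write(f"{pt.x},{pt.y}\n")


def read_hull_csv(path: str | Path) -> ConvexHull:
    return ConvexHull(tuple(read_points(path).points))


def hull_to_wkt(hull: ConvexHull) -> str:
    """WKT POLYGON of the hull ring, closed by repeating the first vertex.

    Degenerate hulls are emitted as POINT / LINESTRING.
    """
    if hull.size == 1:
        (pt,) = hull.vertices
        return f"POINT ({pt.x} {pt.y})"
    if hull.size == 2:
        a, b = hull.vertices
        return f"LINESTRING ({a.x} {a.y}, {b.x} {b.y})"
    ring = list(hull.vertices) + [hull.vertices[0]]
    coords = ", ".join(f"{pt.x} {pt.y}" for pt in ring)
    return f"POLYGON (({coords}))"


def write_hull_wkt(hull: ConvexHull, path: str | Path) -> None:
    Path(path).write_text(hull_to_wkt(hull) + "\n")


def write_extremes_table(t: ExtremesTable, path: str | Path) -> None:
    """Debug dump: one ``u,v`` row per entry, sentinel rows written as-is."""
    with open(path, "w", newline="") as fh:
        fh.write("u,v\n")
        for u, v in t.entries:
            fh.write(f"{u},{v}\n")


def write_chain_csv(chain, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("x,y\n")
        for pt in chain:
            fh.write(f"{pt.x},{pt.y}\n")
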