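"""Binary-image input: hull of a segmented blob's foreground pixels.

Rasterizes a filled superellipse into a PGM mask, reads it back as grid
points (pixel column c, row r -> point (c+1, height-r)), and computes the
hull through the full preconditioning pipeline.  For image data the apply
condition min(p, q) <= n virtually always holds: every occupied column
contributes at least one foreground pixel.
"""

import tempfile
from pathlib import Path

import gridhull as gh
from gridhull.io import image_to_points, read_pgm, write_pgm, hull_to_wkt

mask = gh.generate_mask(gh.ShapeSpec("mask", n=1, p=60, q=40, exponent=4.0))
path = Path(tempfile.mkdtemp()) / "blob.pgm"
write_pgm(mask, path)
print(f"wrote {mask.width} x {mask.height} mask to {path}")

points = image_to_points(read_pgm(path))
result = gh.run(points, "melkman")
print(f"foreground pixels: {points.n}; decision: {result.decision.mode}")
print(f"survivors s = {result.stats.s} "
      f"({100 * result.stats.fraction_removed:.1f}% removed)")
print("hull:", hull_to_wkt(result.hull))
print("-> hull vertex coordinates are in pixel units, y increasing upward.")
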