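"""The three-step hull method and the benchmark harness.

Step 1 measures the bounding box (p, q) and n; step 2 applies the column
min/max reduction along the smaller side iff ``min(p, q) <= n`` (otherwise
it is skipped — sparse data gain nothing); step 3 hands the surviving
points to a convex hull algorithm.  Because the survivors come out as a
simple polygonal chain, Melkman's linear-time algorithm applies directly.

The benchmark harness times the phases separately and reports the speedup
``t_n / (t_r + t_s)``: direct hull time over reduction time plus
reduced-hull time (extraction of survivors is charged to ``t_s``, any
coordinate translation to ``t_r``).
"""

from __future__ import annotations

import gc
import json
import logging
import time
from dataclasses import dataclass
from statistics import median
from typing import Literal

from . import reduction as red
from .chain import build_chain
from .hulls import ConvexHull, akl_toussaint, melkman, monotone_chain
from .reduction import PointSet, PreconditionDecision, ReductionStats

__all__ = ["HullResult", "BenchmarkRecord", "run", "benchmark", "ALGORITHMS"]

log = logging.getLogger(__name__)

Algorithm = Literal["melkman", "monotone_chain", "akl_then_monotone"]
ALGORITHMS: tuple[str, ...] = ("melkman", "monotone_chain", "akl_then_monotone")

#: JSON field order for benchmark records (the on-disk contract)
_RECORD_KEYS = ("n", "p", "q", "sparsity", "s", "fraction_removed", "t_n", "t_r", "t_s", "speedup")


@dataclass(frozen=True)
class HullResult:
    """Hull plus the decision and reduction bookkeeping that produced it."""

    hull: ConvexHull
    decision: PreconditionDecision
    stats: ReductionStats | None
    algorithm: str


@dataclass(frozen=True)
class BenchmarkRecord:
    """Phase timings and counts for one dataset/algorithm pairing.

    ``sparsity`` is min(p, q) / n.  ``speedup`` follows t_n / (t_r + t_s).
    ``decision_mode`` and ``skip_overridden`` are in-memory bookkeeping only;
    the serialized record carries exactly the ten stable keys.
    """

    n: int
    p: int
    q: int
    sparsity: float
    s: int
    fraction_removed: float
    t_n: float
    t_r: float
    t_s: float
    speedup: float
    decision_mode: str = ""
    skip_overridden: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in _RECORD_KEYS}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def _direct_hull(ps: PointSet, algorithm: str) -> ConvexHull:
    """Hull straight from raw points (no chain available on this path)."""
    if algorithm == "akl_then_monotone":
        return monotone_chain(akl_toussaint(ps))
    return monotone_chain(ps)


def run(
    ps: PointSet,
    algorithm: Algorithm = "melkman",
    force_precondition: bool = False,
) -> HullResult:
    """Decide, optionally reduce, and hull.

    On the skip path (sparse data) the hull is computed directly on the
    original points; a Melkman request falls back to the monotone chain
    baseline there, since Melkman needs the chain ordering the reduction
    provides.  ``force_precondition`` applies the reduction even when the
    decision says skip — correctness is unaffected, only speed.
    """
    if len(ps) == 0:
        raise ValueError("cannot run the pipeline on an empty point set")
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    bbox = red.compute_bounding_box(ps)
    decision = red.decide(bbox, ps.n)
    log.info(
        "decision=%s n=%d p=%d q=%d bound=%.4f",
        decision.mode, ps.n, bbox.p, bbox.q, max(0.0, 1.0 - 2 * min(bbox.p, bbox.q) / ps.n),
    )

    if decision.mode == "skip" and not force_precondition:
        effective = algorithm
        if algorithm == "melkman":
            log.info("melkman requires the precondition path; falling back to monotone_chain")
            effective = "monotone_chain"
        return HullResult(_direct_hull(ps, effective), decision, None, effective)

    axis = decision.axis or ("x" if bbox.p <= bbox.q else "y")
    table = red.reduce(ps, bbox, axis)
    st = red.stats(ps.n, table)
    log.info("axis=%s s=%d fraction_removed=%.4f", axis, st.s, st.fraction_removed)
    if algorithm == "melkman":
        hull = melkman(build_chain(table))
    elif algorithm == "monotone_chain":
        hull = monotone_chain(red.valid_points(table))
    else:
        hull = monotone_chain(akl_toussaint(red.valid_points(table)))
    return HullResult(hull, decision, st, algorithm)


def benchmark(
    ps: PointSet,
    algorithm: Algorithm = "melkman",
    repeats: int = 5,
    force_precondition: bool = False,
) -> BenchmarkRecord:
    """Median wall-clock phase timings over ``repeats`` runs.

    ``t_n``: direct hull on all n points (monotone chain, or the throw-away
    filter plus monotone chain).  ``t_r``: bounding box, decision and the
    one-pass reduction.  ``t_s``: survivor extraction, chain build and hull
    on the reduced set.  Counts are deterministic across repeats; only the
    timings vary.  Garbage collection is paused during timed sections.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if len(ps) == 0:
        raise ValueError("cannot benchmark an empty point set")

    bbox = red.compute_bounding_box(ps)
    decision = red.decide(bbox, ps.n)
    skip_overridden = decision.mode == "skip" and force_precondition
    axis: red.Axis = decision.axis or ("x" if bbox.p <= bbox.q else "y")

    t_n_samples, t_r_samples, t_s_samples = [], [], []
    gc_was_enabled = gc.isenabled()
    gc.disable()
    try:
        for _ in range(repeats):
            tic = time.perf_counter()
            _direct_hull(ps, algorithm)
            t_n_samples.append(time.perf_counter() - tic)

            tic = time.perf_counter()
            b = red.compute_bounding_box(ps)
            red.decide(b, ps.n)
            table = red.reduce(ps, b, axis)
            t_r_samples.append(time.perf_counter() - tic)

            tic = time.perf_counter()
            if algorithm == "melkman":
                hull = melkman(build_chain(table))
            elif algorithm == "monotone_chain":
                hull = monotone_chain(red.valid_points(table))
            else:
                hull = monotone_chain(akl_toussaint(red.valid_points(table)))
            t_s_samples.append(time.perf_counter() - tic)
            del hull
    finally:
        if gc_was_enabled:
            gc.enable()

    st = red.stats(ps.n, table)
    t_n, t_r, t_s = median(t_n_samples), median(t_r_samples), median(t_s_samples)
    denom = t_r + t_s
    return BenchmarkRecord(
        n=ps.n,
        p=bbox.p,
        q=bbox.q,
        sparsity=min(bbox.p, bbox.q) / ps.n,
        s=st.s,
        fraction_removed=st.fraction_removed,
        t_n=t_n,
        t_r=t_r,
        t_s=t_s,
        speedup=(t_n / denom) if denom > 0 else float("inf"),
        decision_mode=decision.mode,
        skip_overridden=skip_overridden,
    )
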