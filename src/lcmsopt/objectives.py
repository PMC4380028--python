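"""Fitness objectives of a targeted LC-MS/MS run and Pareto dominance.

Three objectives score each analysis:

* ``analysis_time`` (minutes, minimize) — the retention time of the last
  eluting *detected* target, not the instrument's total run time.  A run
  detecting nothing is penalized with the run's maximum recorded time, so
  empty chromatograms never look fast.
* ``n_detected`` (count, maximize) — targets whose peak cleared detection.
* ``total_area`` (counts*minutes, maximize) — summed area of those peaks.

Objectives are kept on raw scales; dominance and the optimizer's hypergrid
handle scale differences.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple, Sequence

from .peak_detection import Peak

__all__ = [
    "ObjectiveVector",
    "SENSES",
    "OBJECTIVE_REGISTRY",
    "evaluate_objectives",
    "dominates",
    "nondominated_front",
]

#: optimization sense per objective, in field order: -1 minimize, +1 maximize
SENSES = (-1, +1, +1)


class ObjectiveVector(NamedTuple):
    analysis_time: float  # minutes; minimize
    n_detected: int  # count; maximize
    total_area: float  # counts*minutes; maximize


def evaluate_objectives(
    peaks: Mapping[str, Peak | None], run_max_time: float
) -> ObjectiveVector:
    """Score one analysis from its per-target detection results.

    ``peaks`` must cover the full target list (one entry per target, ``None``
    for misses).  With zero detections ``analysis_time`` is set to
    ``run_max_time`` as a worst-case penalty.
    """
    detected = [p for p in peaks.values() if p is not None]
    n = len(detected)
    if n == 0:
        return ObjectiveVector(float(run_max_time), 0, 0.0)
    return ObjectiveVector(
        analysis_time=max(p.apex_rt for p in detected),
        n_detected=n,
        total_area=sum(p.area for p in detected),
    )


def dominates(a: ObjectiveVector, b: ObjectiveVector) -> bool:
    """True iff ``a`` Pareto-dominates ``b``: no worse in every objective
    under its sense and strictly better in at least one."""
    no_worse = (
        a.analysis_time <= b.analysis_time
        and a.n_detected >= b.n_detected
        and a.total_area >= b.total_area
    )
    strictly_better = (
        a.analysis_time < b.analysis_time
        or a.n_detected > b.n_detected
        or a.total_area > b.total_area
    )
    return no_worse and strictly_better


def nondominated_front(points: Iterable[ObjectiveVector]) -> list[ObjectiveVector]:
    """Members not dominated by any other member; duplicates retained.

    Order of the input is preserved.  Duplicate vectors never dominate each
    other, so all copies of a non-dominated vector are kept.
    """
    pts = list(points)
    return [p for p in pts if not any(dominates(q, p) for q in pts)]


#: named objectives with senses, resolvable from the experiment
#: configuration; alternates can be registered without touching the
#: optimizer (each maps (peaks, run_max_time) -> scalar)
OBJECTIVE_REGISTRY: dict[str, dict] = {
    "analysis_time": {
        "sense": "minimize",
        "unit": "minutes",
        "fn": lambda peaks, run_max_time: evaluate_objectives(peaks, run_max_time).analysis_time,
    },
    "n_detected": {
        "sense": "maximize",
        "unit": "count",
        "fn": lambda peaks, run_max_time: evaluate_objectives(peaks, run_max_time).n_detected,
    },
    "total_area": {
        "sense": "maximize",
        "unit": "counts*minutes",
        "fn": lambda peaks, run_max_time: evaluate_objectives(peaks, run_max_time).total_area,
    },
}
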