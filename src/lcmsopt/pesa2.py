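"""PESA-II: Pareto envelope-based selection over discretized parameter grids.

The optimizer is built for closed-loop experimentation, where every fitness
evaluation is a physical (or simulated) LC-MS/MS analysis and the budget is
tens to hundreds of runs.  It keeps a bounded external archive of mutually
non-dominated solutions, bins archive members into an adaptive hypergrid
over objective space, selects parents by binary tournament between grid
boxes (less crowded box wins), and evicts from the most crowded box when
the archive overflows.

Parameters are discretized — each has minimum, maximum and step — so a
solution's genotype is a vector of integer level indices.  This makes the
search space finite and exhaustive enumeration (:func:`brute_force_front`)
an exact oracle on small spaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .objectives import ObjectiveVector, dominates

__all__ = [
    "ParameterSpec",
    "Solution",
    "ArchiveEntry",
    "GASettings",
    "Hypergrid",
    "random_solution",
    "box_of",
    "update_archive",
    "select_parent",
    "crossover",
    "mutate",
    "brute_force_front",
]


@dataclass(frozen=True)
class ParameterSpec:
    """One discretized LC or MS control parameter."""

    name: str
    minimum: float
    maximum: float
    step: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("parameter name must be non-empty")
        if self.minimum > self.maximum:
            raise ValueError(f"parameter {self.name!r}: minimum > maximum")
        if self.step <= 0:
            raise ValueError(f"parameter {self.name!r}: step must be positive")

    @property
    def level_count(self) -> int:
        span = (self.maximum - self.minimum) / self.step
        # tolerate float error when span is (near-)integral
        return int(math.floor(span + 1e-9)) + 1

    def value_of(self, level: int) -> float:
        if not (0 <= level < self.level_count):
            raise ValueError(
                f"parameter {self.name!r}: level {level} outside [0, {self.level_count})"
            )
        return min(self.minimum + level * self.step, self.maximum)


@dataclass(frozen=True)
class Solution:
    """A point in the search grid: integer level per parameter."""

    genotype: tuple[int, ...]
    space: tuple[ParameterSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotype", tuple(int(g) for g in self.genotype))
        object.__setattr__(self, "space", tuple(self.space))
        if len(self.genotype) != len(self.space):
            raise ValueError("genotype length must equal parameter count")
        for g, spec in zip(self.genotype, self.space):
            if not (0 <= g < spec.level_count):
                raise ValueError(
                    f"gene {g} out of range for parameter {spec.name!r} "
                    f"({spec.level_count} levels)"
                )

    @property
    def phenotype(self) -> dict[str, float]:
        """Decoded native-unit parameter values."""
        return {spec.name: spec.value_of(g) for g, spec in zip(self.genotype, self.space)}


@dataclass(frozen=True)
class ArchiveEntry:
    solution: Solution
    objectives: ObjectiveVector
    generation: int = 0
    run_id: str = ""
    mzml_path: str | None = None

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in self.objectives):
            raise ValueError("objectives must be finite")


@dataclass(frozen=True)
class GASettings:
    """Optimizer settings; defaults sized for ~200-analysis campaigns."""

    archive_capacity: int = 100
    initial_runs: int = 20
    runs_per_generation: int = 2
    max_runs: int = 200
    crossover_prob: float = 0.9
    mutation_prob: float | None = None  # None -> 1 / n_parameters
    grid_divisions: int = 8
    seed: int = 0
    memoize: bool = False  # skip re-evaluating repeated genotypes (noise-free use)

    def __post_init__(self) -> None:
        if self.archive_capacity < 1:
            raise ValueError("archive_capacity must be >= 1")
        if self.initial_runs < 1 or self.runs_per_generation < 1:
            raise ValueError("initial_runs and runs_per_generation must be >= 1")
        if self.max_runs < self.initial_runs:
            raise ValueError("max_runs must be >= initial_runs")
        if not (0 <= self.crossover_prob <= 1):
            raise ValueError("crossover_prob must lie in [0, 1]")
        if self.mutation_prob is not None and not (0 <= self.mutation_prob <= 1):
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.grid_divisions < 1:
            raise ValueError("grid_divisions must be >= 1")

    def mutation_prob_for(self, n_parameters: int) -> float:
        if self.mutation_prob is not None:
            return self.mutation_prob
        return 1.0 / max(n_parameters, 1)


# ---------------------------------------------------------------------------
# hypergrid


@dataclass
class Hypergrid:
    """Adaptive objective-space grid used for crowding.

    Bounds are recomputed from the current archive extent whenever
    membership changes; a degenerate dimension (all members equal)
    collapses to a single bin.
    """

    divisions: int
    lower: tuple[float, float, float] = (0.0, 0.0, 0.0)
    upper: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @classmethod
    def fit(cls, points: Sequence[ObjectiveVector], divisions: int) -> "Hypergrid":
        if not points:
            raise ValueError("cannot fit a hypergrid to an empty archive")
        arr = np.asarray([tuple(p) for p in points], dtype=np.float64)
        return cls(
            divisions=divisions,
            lower=tuple(arr.min(axis=0)),
            upper=tuple(arr.max(axis=0)),
        )


def box_of(objectives: ObjectiveVector, grid: Hypergrid) -> tuple[int, int, int]:
    """Grid-box coordinates of an objective vector.

    Per dimension: ``min(divisions-1, floor(divisions * (v - lo) / (hi - lo)))``
    with degenerate dimensions mapping to 0.
    """
    coords = []
    for v, lo, hi in zip(objectives, grid.lower, grid.upper):
        if hi <= lo:
            coords.append(0)
        else:
            c = int(math.floor(grid.divisions * (v - lo) / (hi - lo)))
            coords.append(min(grid.divisions - 1, max(c, 0)))
    return tuple(coords)


def _boxes(archive: Sequence[ArchiveEntry], grid: Hypergrid) -> dict[tuple[int, int, int], list[int]]:
    out: dict[tuple[int, int, int], list[int]] = {}
    for i, entry in enumerate(archive):
        out.setdefault(box_of(entry.objectives, grid), []).append(i)
    return out


def update_archive(
    archive: Sequence[ArchiveEntry],
    candidate: ArchiveEntry,
    settings: GASettings,
) -> list[ArchiveEntry]:
    """Insert a candidate into a mutually non-dominated archive.

    A candidate dominated by any member leaves the archive unchanged.
    Otherwise it is inserted, every member it dominates is dropped, and if
    the archive then exceeds capacity one member of a maximally crowded
    hypergrid box is evicted (uniformly; the fresh candidate is spared
    unless it is the sole occupant of every maximal box).  Eviction
    randomness is seeded by ``settings.seed`` and the archive contents, so
    the update is deterministic given its inputs.
    """
    if any(dominates(m.objectives, candidate.objectives) for m in archive):
        return list(archive)
    kept = [m for m in archive if not dominates(candidate.objectives, m.objectives)]
    kept.append(candidate)
    if len(kept) <= settings.archive_capacity:
        return kept

    grid = Hypergrid.fit([m.objectives for m in kept], settings.grid_divisions)
    boxes = _boxes(kept, grid)
    max_squeeze = max(len(v) for v in boxes.values())
    pool = [
        i
        for members in boxes.values()
        if len(members) == max_squeeze
        for i in members
    ]
    cand_idx = len(kept) - 1
    protected = [i for i in pool if i != cand_idx]
    if protected:
        pool = protected
    # deterministic eviction: seed mixes settings.seed with archive state
    h = hash((settings.seed, tuple((m.objectives, m.solution.genotype) for m in kept)))
    rng = np.random.default_rng(abs(h) % (2**32))
    evict = int(rng.choice(pool))
    return [m for i, m in enumerate(kept) if i != evict]


def select_parent(
    archive: Sequence[ArchiveEntry],
    grid: Hypergrid,
    rng: np.random.Generator,
) -> ArchiveEntry:
    """Region-based binary tournament selection.

    Two occupied boxes are drawn uniformly with replacement; the one with
    the smaller squeeze factor (occupancy) wins, ties resolved uniformly;
    the parent is a uniform member of the winning box.
    """
    if not archive:
        raise RuntimeError("cannot select a parent from an empty archive")
    boxes = _boxes(archive, grid)
    keys = sorted(boxes)
    i1, i2 = rng.integers(0, len(keys), size=2)
    b1, b2 = keys[int(i1)], keys[int(i2)]
    s1, s2 = len(boxes[b1]), len(boxes[b2])
    if s1 < s2:
        winner = b1
    elif s2 < s1:
        winner = b2
    else:
        winner = b1 if rng.random() < 0.5 else b2
    members = boxes[winner]
    return archive[members[int(rng.integers(0, len(members)))]]


# ---------------------------------------------------------------------------
# variation operators


def random_solution(
    space: Sequence[ParameterSpec], rng: np.random.Generator
) -> Solution:
    """Uniform random genotype: each gene drawn independently over its levels."""
    if not space:
        raise ValueError("parameter space must be non-empty")
    genotype = tuple(int(rng.integers(0, spec.level_count)) for spec in space)
    return Solution(genotype=genotype, space=tuple(space))


def crossover(
    p1: Solution, p2: Solution, prob: float, rng: np.random.Generator
) -> Solution:
    """Uniform crossover with probability ``prob``; otherwise a copy of ``p1``."""
    if p1.space != p2.space:
        raise ValueError("parents live in different parameter spaces")
    if rng.random() >= prob:
        return Solution(genotype=p1.genotype, space=p1.space)
    genotype = tuple(
        g2 if rng.random() < 0.5 else g1 for g1, g2 in zip(p1.genotype, p2.genotype)
    )
    return Solution(genotype=genotype, space=p1.space)


def mutate(
    s: Solution, prob: float, space: Sequence[ParameterSpec], rng: np.random.Generator
) -> Solution:
    """Resampling mutation: each gene is, with probability ``prob``,
    replaced by a uniform draw over its levels (possibly the same level)."""
    genotype = list(s.genotype)
    for i, spec in enumerate(space):
        if rng.random() < prob:
            genotype[i] = int(rng.integers(0, spec.level_count))
    return Solution(genotype=tuple(genotype), space=tuple(space))


# ---------------------------------------------------------------------------
# exhaustive oracle

#: refuse enumeration beyond this many genotypes
BRUTE_FORCE_LIMIT = 100_000


def brute_force_front(
    space: Sequence[ParameterSpec],
    evaluator: Callable[[Solution], ObjectiveVector],
) -> list[tuple[Solution, ObjectiveVector]]:
    """Enumerate every genotype, evaluate it, return the exact Pareto set.

    Feasible only on small discretized spaces (<= ``BRUTE_FORCE_LIMIT``
    combinations); used as the ground-truth front on the simulator, where —
    unlike on hardware — exhaustive search is affordable.
    """
    total = math.prod(spec.level_count for spec in space)
    if total > BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"search space has {total} combinations; brute force capped at {BRUTE_FORCE_LIMIT}"
        )
    space = tuple(space)
    evaluated: list[tuple[Solution, ObjectiveVector]] = []

    def rec(prefix: tuple[int, ...]) -> None:
        if len(prefix) == len(space):
            sol = Solution(genotype=prefix, space=space)
            evaluated.append((sol, evaluator(sol)))
            return
        for level in range(space[len(prefix)].level_count):
            rec(prefix + (level,))

    rec(())
    return [
        (s, o)
        for s, o in evaluated
        if not any(dominates(o2, o) for _, o2 in evaluated)
    ]
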