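import itertools
import math

import numpy as np
import pytest

from lcmsopt.objectives import ObjectiveVector, dominates
from lcmsopt.pesa2 import (
    ArchiveEntry,
    GASettings,
    Hypergrid,
    ParameterSpec,
    Solution,
    box_of,
    brute_force_front,
    crossover,
    mutate,
    random_solution,
    select_parent,
    update_archive,
)

SPACE5 = (ParameterSpec("p", 0.0, 4.0, 1.0),)
SPACE8 = tuple(ParameterSpec(f"p{i}", 0.0, 4.0, 1.0) for i in range(8))


def _entry(time, n, area, genotype=(0,), space=SPACE5, gen=1):
    return ArchiveEntry(
        Solution(genotype, space), ObjectiveVector(time, n, area), generation=gen
    )


class TestParameterSpec:
    @pytest.mark.parametrize(
        "lo,hi,step,expected",
        [
            (0.0, 4.0, 1.0, 5),
            (0.0, 1.0, 0.1, 11),  # float-noise span
            (0.0, 0.3, 0.1, 4),
            (3.0, 3.0, 0.5, 1),  # degenerate single level
            (4.0, 16.0, 3.0, 5),
        ],
    )
    def test_level_count(self, lo, hi, step, expected):
        assert ParameterSpec("p", lo, hi, step).level_count == expected

    def test_decoded_values_stay_in_range(self):
        spec = ParameterSpec("p", 0.0, 1.0, 0.1)
        values = [spec.value_of(i) for i in range(spec.level_count)]
        assert values[0] == 0.0
        assert values[-1] <= 1.0
        assert np.allclose(values, np.arange(11) * 0.1)

    @pytest.mark.parametrize("kwargs", [
        dict(minimum=2.0, maximum=1.0, step=0.5),
        dict(minimum=0.0, maximum=1.0, step=0.0),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ParameterSpec("p", **kwargs)

    def test_solution_gene_bounds_checked(self):
        with pytest.raises(ValueError):
            Solution((5,), SPACE5)


class TestRandomSolution:
    def test_single_level_parameter_always_zero(self):
        space = (ParameterSpec("p", 1.0, 1.0, 0.5),)
        rng = np.random.default_rng(0)
        assert all(random_solution(space, rng).genotype == (0,) for _ in range(50))

    def test_uniform_law(self):
        rng = np.random.default_rng(1)
        counts = np.zeros(5)
        n = 100_000
        for _ in range(n):
            counts[random_solution(SPACE5, rng).genotype[0]] += 1
        freqs = counts / n
        assert np.all(np.abs(freqs - 0.2) <= 0.01)

    def test_seeded_determinism(self):
        a = [random_solution(SPACE8, np.random.default_rng(3)).genotype for _ in range(1)]
        b = [random_solution(SPACE8, np.random.default_rng(3)).genotype for _ in range(1)]
        assert a == b


class TestHypergrid:
    def test_upper_edge_clamped(self):
        grid = Hypergrid(divisions=5, lower=(0, 0, 0), upper=(10, 10, 10))
        assert box_of(ObjectiveVector(10, 10, 10), grid) == (4, 4, 4)

    def test_lower_bound_maps_to_zero(self):
        grid = Hypergrid(divisions=5, lower=(0, 0, 0), upper=(10, 10, 10))
        assert box_of(ObjectiveVector(0, 0, 0), grid) == (0, 0, 0)

    def test_degenerate_dimension_collapses(self):
        grid = Hypergrid(divisions=5, lower=(0, 3, 0), upper=(10, 3, 10))
        assert box_of(ObjectiveVector(5, 3, 5), grid)[1] == 0

    def test_binning_matches_brute_force_rebinning(self):
        rng = np.random.default_rng(5)
        pts = [
            ObjectiveVector(float(t), int(n), float(a))
            for t, n, a in zip(
                rng.uniform(0, 10, 100), rng.integers(0, 7, 100), rng.uniform(0, 1e4, 100)
            )
        ]
        grid = Hypergrid.fit(pts, divisions=8)
        # independent rebinning oracle
        arr = np.array([tuple(p) for p in pts])
        lo, hi = arr.min(axis=0), arr.max(axis=0)
        for p in pts:
            expected = tuple(
                0 if h <= l else min(7, int(math.floor(8 * (v - l) / (h - l))))
                for v, l, h in zip(p, lo, hi)
            )
            assert box_of(p, grid) == expected


class TestUpdateArchive:
    SETTINGS = GASettings(archive_capacity=10, grid_divisions=4)

    def test_empty_archive_accepts_any_candidate(self):
        cand = _entry(1.0, 6, 100.0)
        assert update_archive([], cand, self.SETTINGS) == [cand]

    def test_dominated_candidate_leaves_archive_unchanged(self):
        incumbent = _entry(1.0, 6, 1000.0)
        cand = _entry(2.0, 5, 900.0, genotype=(1,))
        assert update_archive([incumbent], cand, self.SETTINGS) == [incumbent]

    def test_candidate_removes_members_it_dominates(self):
        weak1 = _entry(3.0, 4, 100.0)
        weak2 = _entry(2.5, 5, 200.0, genotype=(1,))
        strong = _entry(1.0, 6, 900.0, genotype=(2,))
        out = update_archive([weak1, weak2], strong, self.SETTINGS)
        assert out == [strong]

    def test_capacity_eviction_comes_from_most_crowded_box(self):
        rng = np.random.default_rng(9)
        settings = GASettings(archive_capacity=10, grid_divisions=4)
        archive = []
        history = []
        for i in range(200):
            # times decreasing with areas increasing => many non-dominated
            t = float(rng.uniform(0, 10))
            cand = _entry(t, 6, 1000.0 * t + rng.uniform(0, 5), genotype=(i % 5,))
            before = list(archive)
            archive = update_archive(archive, cand, settings)
            history.append(cand)
            # soundness after every update
            assert len(archive) <= settings.archive_capacity
            for a, b in itertools.combinations(archive, 2):
                assert not dominates(a.objectives, b.objectives)
                assert not dominates(b.objectives, a.objectives)
            # eviction legality: the evicted member came from a maximal box
            if len(before) == settings.archive_capacity and not any(
                dominates(m.objectives, cand.objectives) for m in before
            ):
                survivors_plus_evicted = before + [cand]
                evicted = [m for m in survivors_plus_evicted if m not in archive]
                if evicted:
                    kept_candidates = [
                        m for m in survivors_plus_evicted
                        if not dominates(cand.objectives, m.objectives) or m is cand
                    ]
                    grid = Hypergrid.fit(
                        [m.objectives for m in kept_candidates], settings.grid_divisions
                    )
                    occupancy = {}
                    for m in kept_candidates:
                        occupancy.setdefault(box_of(m.objectives, grid), []).append(m)
                    max_squeeze = max(len(v) for v in occupancy.values())
                    for m in evicted:
                        box = box_of(m.objectives, grid)
                        assert len(occupancy[box]) == max_squeeze

    def test_update_is_deterministic(self):
        rng = np.random.default_rng(13)
        settings = GASettings(archive_capacity=5, grid_divisions=4)
        cands = [
            _entry(float(t), 6, float(a), genotype=(i % 5,))
            for i, (t, a) in enumerate(zip(rng.uniform(0, 10, 50), rng.uniform(0, 1e4, 50)))
        ]
        def run():
            archive = []
            for c in cands:
                archive = update_archive(archive, c, settings)
            return [(e.solution.genotype, e.objectives) for e in archive]
        assert run() == run()


class TestSelectParent:
    def test_single_member(self):
        e = _entry(1.0, 6, 100.0)
        grid = Hypergrid.fit([e.objectives], 4)
        assert select_parent([e], grid, np.random.default_rng(0)) is e

    def test_empty_archive_is_error(self):
        grid = Hypergrid(divisions=4)
        with pytest.raises(RuntimeError):
            select_parent([], grid, np.random.default_rng(0))

    def test_lone_member_of_sparse_box_selected_three_quarters(self):
        """Two occupied boxes with squeeze 3 and 1: enumerating the four
        equiprobable box-tournament outcomes, the sparse box wins 3 of 4."""
        crowded = [
            _entry(0.1 + 0.01 * i, 6, 100.0 + i, genotype=(i,)) for i in range(3)
        ]
        lone = _entry(9.9, 6, 5000.0, genotype=(4,))
        archive = crowded + [lone]
        grid = Hypergrid.fit([e.objectives for e in archive], divisions=2)
        assert box_of(lone.objectives, grid) != box_of(crowded[0].objectives, grid)
        rng = np.random.default_rng(2)
        n = 100_000
        hits = sum(select_parent(archive, grid, rng) is lone for _ in range(n))
        assert hits / n == pytest.approx(0.75, abs=0.02)

    def test_single_box_degenerates_to_uniform(self):
        members = [_entry(1.0, 6, 100.0, genotype=(i,)) for i in range(4)]
        grid = Hypergrid.fit([e.objectives for e in members], 4)
        rng = np.random.default_rng(3)
        counts = np.zeros(4)
        n = 40_000
        for _ in range(n):
            counts[select_parent(members, grid, rng).solution.genotype[0]] += 1
        assert np.all(np.abs(counts / n - 0.25) <= 0.02)


class TestVariationOperators:
    def test_identical_parents_yield_identical_child(self):
        p = Solution((1, 2, 3, 4, 0, 1, 2, 3), SPACE8)
        child = crossover(p, p, 1.0, np.random.default_rng(0))
        assert child.genotype == p.genotype

    def test_crossover_prob_zero_copies_first_parent(self):
        p1 = Solution((0,) * 8, SPACE8)
        p2 = Solution((4,) * 8, SPACE8)
        child = crossover(p1, p2, 0.0, np.random.default_rng(0))
        assert child.genotype == p1.genotype

    def test_crossover_space_mismatch_rejected(self):
        with pytest.raises(ValueError):
            crossover(Solution((0,), SPACE5), Solution((0,) * 8, SPACE8), 1.0,
                      np.random.default_rng(0))

    def test_uniform_crossover_gene_law(self):
        p1 = Solution((0,) * 8, SPACE8)
        p2 = Solution((4,) * 8, SPACE8)
        rng = np.random.default_rng(4)
        n = 100_000
        from_p2 = np.zeros(8)
        for _ in range(n):
            child = crossover(p1, p2, 1.0, rng)
            from_p2 += np.asarray(child.genotype) == 4
        assert np.all(np.abs(from_p2 / n - 0.5) <= 0.01)

    def test_mutation_prob_zero_is_identity(self):
        s = Solution((1, 2, 3, 4, 0, 1, 2, 3), SPACE8)
        assert mutate(s, 0.0, SPACE8, np.random.default_rng(0)).genotype == s.genotype

    def test_single_level_gene_never_changes(self):
        space = (ParameterSpec("p", 2.0, 2.0, 1.0),)
        s = Solution((0,), space)
        assert mutate(s, 1.0, space, np.random.default_rng(0)).genotype == (0,)

    def test_resampling_mutation_law(self):
        s = Solution((0,), SPACE5)
        rng = np.random.default_rng(6)
        n = 100_000
        counts = np.zeros(5)
        for _ in range(n):
            counts[mutate(s, 1.0, SPACE5, rng).genotype[0]] += 1
        assert np.all(np.abs(counts / n - 0.2) <= 0.01)


class TestBruteForceFront:
    def test_single_point_space(self):
        space = (ParameterSpec("p", 1.0, 1.0, 1.0),)
        front = brute_force_front(space, lambda s: ObjectiveVector(1.0, 1, 1.0))
        assert len(front) == 1

    def test_monotone_single_objective(self):
        # time improves with the level; count/area constant => unique optimum
        front = brute_force_front(
            SPACE5, lambda s: ObjectiveVector(10.0 - s.genotype[0], 1, 1.0)
        )
        assert len(front) == 1
        assert front[0][0].genotype == (4,)

    def test_refuses_oversized_space(self):
        big = tuple(ParameterSpec(f"p{i}", 0.0, 9.0, 1.0) for i in range(6))  # 1e6
        with pytest.raises(ValueError, match="combinations"):
            brute_force_front(big, lambda s: ObjectiveVector(1.0, 1, 1.0))

    def test_exact_front_on_default_simulator(self, parameter_space, noise_free_evaluator):
        """On the 125-point noise-free space the enumerated front matches an
        independent all-pairs dominance check over every evaluation."""
        front = brute_force_front(parameter_space, noise_free_evaluator)
        assert len({o for _, o in front}) >= 3
        # independent oracle: evaluate everything, filter by all-pairs scan
        all_evals = []
        levels = [range(p.level_count) for p in parameter_space]
        for genotype in itertools.product(*levels):
            sol = Solution(genotype, tuple(parameter_space))
            all_evals.append((genotype, noise_free_evaluator(sol)))
        expected = {
            g: o
            for g, o in all_evals
            if not any(dominates(o2, o) for _, o2 in all_evals)
        }
        assert {s.genotype for s, _ in front} == set(expected)
        assert {o for _, o in front} == set(expected.values())
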