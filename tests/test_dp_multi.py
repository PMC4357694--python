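"""Multi-codon dynamic program and primer accounting."""

import pytest

from dcopt.dp_multi import optimize_multi
from dcopt.dp_single import optimize_single
from dcopt.errors import ConfigError, InfeasibleLibraryError
from dcopt.fixtures import generate_fixture
from dcopt.library import (
    Limits,
    PrimerLimits,
    StretchLayout,
    count_primers,
)
from dcopt.oracle import brute_force_optimize

from conftest import manual_solution, sample_candidates


class TestPrimerAccounting:
    def test_published_three_codon_solution_uses_fifteen_primers(
        self, surface_problem, surface_tables_lp3
    ):
        solution, _ = optimize_multi(
            list(surface_problem.positions),
            surface_problem.layout,
            Limits(surface_problem.diversity_limit),
            PrimerLimits(3, 15, 15),
            tables=surface_tables_lp3,
        )
        per_stretch, total = count_primers(solution, surface_problem.layout)
        assert per_stretch == (9, 6)
        assert total == 15

    def test_all_singleton_solution_needs_one_primer_per_stretch(
        self, surface_problem
    ):
        sets = {p.label: ("NNK",) for p in surface_problem.positions}
        solution = manual_solution(surface_problem.positions, sets)
        per_stretch, total = count_primers(solution, surface_problem.layout)
        assert per_stretch == (1, 1)
        assert total == len(surface_problem.layout.stretches)

    def test_layout_mismatch_is_an_error(self, surface_problem):
        sets = {p.label: ("NNK",) for p in surface_problem.positions}
        solution = manual_solution(surface_problem.positions, sets)
        other = StretchLayout((("999",),))
        with pytest.raises(ConfigError, match="999"):
            count_primers(solution, other)


class TestLimitsValidation:
    def test_primer_limit_ordering_enforced(self):
        with pytest.raises(ConfigError, match="<="):
            PrimerLimits(3, 2, 5)

    def test_total_must_cover_stretches(self, surface_problem):
        with pytest.raises(ConfigError, match="stretches"):
            optimize_multi(
                list(surface_problem.positions),
                surface_problem.layout,
                Limits(10**9),
                PrimerLimits(1, 1, 1),
            )

    def test_layout_must_match_position_order(self, surface_problem):
        bad = StretchLayout((("330", "331", "332"),
                             ("268", "269", "270", "271", "272", "276")))
        with pytest.raises(ConfigError, match="order"):
            optimize_multi(
                list(surface_problem.positions), bad, Limits(10**9),
                PrimerLimits(2, 4, 4),
            )


class TestAgainstSingle:
    @pytest.mark.parametrize("seed", range(6))
    def test_one_codon_limit_reduces_to_single_dp(self, seed):
        specs, layout = generate_fixture(
            3, stretch_sizes=[2, 1], symbols_per_position=3,
            total_per_position=15, seed=seed,
        )
        candidates = sample_candidates(seed + 50, 20)
        limits = Limits(5000 if seed % 2 else 64**3)
        single, _ = optimize_single(specs, limits, candidates=candidates)
        multi, _ = optimize_multi(
            specs, layout, limits, PrimerLimits(1, 2, 2), candidates=candidates
        )
        assert (multi.error, multi.size) == (single.error, single.size)


class TestAgainstBruteForce:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        specs, layout = generate_fixture(
            2, stretch_sizes=[1, 1] if seed % 2 else [2],
            symbols_per_position=3, total_per_position=12, seed=seed,
        )
        candidates = sample_candidates(seed + 100, 10)
        pl = PrimerLimits(2, 2 + seed % 3, 2 + seed % 3 + seed % 2)
        limits = Limits([300, 64**2][seed % 2])
        try:
            ref = brute_force_optimize(
                specs, limits, layout=layout, primer_limits=pl,
                candidates=[candidates] * 2,
            )
        except InfeasibleLibraryError:
            with pytest.raises(InfeasibleLibraryError):
                optimize_multi(specs, layout, limits, pl, candidates=candidates)
            return
        ours, _ = optimize_multi(specs, layout, limits, pl, candidates=candidates)
        assert (ours.error, ours.size) == (ref.error, ref.size)


class TestMonotonicity:
    def test_raising_any_limit_never_raises_error(self):
        specs, layout = generate_fixture(
            3, stretch_sizes=[2, 1], symbols_per_position=4,
            total_per_position=20, seed=17,
        )
        candidates = sample_candidates(17, 15)

        def err(L=2000, lp=1, ls=2, lt=2):
            sol, _ = optimize_multi(
                specs, layout, Limits(L), PrimerLimits(lp, ls, lt),
                candidates=candidates,
            )
            return sol.error

        base = err()
        assert err(L=64**3) <= base
        assert err(lp=2) <= base
        assert err(lp=2, ls=3, lt=3) <= err(lp=2)
        assert err(lp=2, ls=3, lt=4) <= err(lp=2, ls=3, lt=3)


class TestSelfConsistency:
    def test_solution_and_primer_counts_recompute(self, lov2_problem, lov2_tables_lp3):
        positions = list(lov2_problem.positions)
        solution, _ = optimize_multi(
            positions, lov2_problem.layout, Limits(lov2_problem.diversity_limit),
            PrimerLimits(2, 10, 10), tables=lov2_tables_lp3,
        )
        assert solution.recompute(positions) == (solution.error, solution.size)
        per_stretch, total = count_primers(solution, lov2_problem.layout)
        assert per_stretch == solution.primers_per_stretch
        assert total == solution.primers_total <= 10
        assert all(ps <= 10 for ps in per_stretch)
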