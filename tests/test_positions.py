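"""Position error model, admissibility, coverage classes, s_i tables."""

import pytest

from dcopt.errors import InfeasiblePositionError
from dcopt.oracle import brute_force_position_table
from dcopt.positions import (
    PositionSpec,
    admissible_codons,
    build_position_table,
    codon_error,
    codon_set_error,
    codon_set_size,
    coverage_class_representatives,
)

from conftest import sample_candidates


def by_label(problem):
    return {p.label: p for p in problem.positions}


class TestPositionSpec:
    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="non-negative"):
            PositionSpec("x", {"A": -1})

    def test_rejects_unknown_symbol(self):
        with pytest.raises(ValueError, match="unknown symbol"):
            PositionSpec("x", {"Z": 1})

    def test_rejects_required_and_forbidden_overlap(self):
        with pytest.raises(ValueError, match="required and forbidden"):
            PositionSpec("x", {"A": 1}, required={"G"}, forbidden={"G"})

    def test_rejects_forbidding_counted_symbol(self):
        with pytest.raises(ValueError, match="may not be forbidden"):
            PositionSpec("x", {"A": 1}, forbidden={"A"})


class TestErrorFunction:
    def test_published_single_codon_errors(self, surface_problem):
        pos = by_label(surface_problem)
        assert codon_error(pos["269"], "RBT") == 39
        assert codon_error(pos["272"], "DYG") == 1

    def test_covering_codon_has_zero_error(self):
        spec = PositionSpec("x", {"C": 5, "W": 3, "Y": 2})
        # NNN covers everything and nothing is penalized.
        assert codon_error(spec, "NNN") == 0

    def test_penalty_charged_when_symbol_produced(self):
        spec = PositionSpec("x", {"C": 5}, penalties={"*": 7})
        assert codon_error(spec, "TGT") == 0  # C only
        assert codon_error(spec, "TGW") == 7  # C plus the TGA stop

    def test_set_error_uses_union(self, lov2_problem):
        pos = by_label(lov2_problem)
        assert codon_set_error(pos["529"], {"CWC", "RBG"}) == 1

    def test_set_error_on_interface_pair(self, surface_problem):
        pos = by_label(surface_problem)
        assert codon_set_error(pos["269"], {"DBG", "RAM"}) == 4

    def test_singleton_set_equals_codon_error(self, surface_problem):
        pos = by_label(surface_problem)
        assert codon_set_error(pos["269"], {"RBT"}) == codon_error(pos["269"], "RBT")

    def test_penalty_charged_once_per_symbol_in_union(self):
        spec = PositionSpec("x", {"C": 5}, penalties={"*": 7})
        # Both TGW and TAR produce stops; the penalty applies once.
        assert codon_set_error(spec, {"TGW", "TAR"}) == 7

    @pytest.mark.parametrize(
        "codons, size", [({"TRT", "TGG"}, 3), ({"DBG", "RAM"}, 13), ({"NNK"}, 32)]
    )
    def test_set_size_sums_degeneracies(self, codons, size):
        assert codon_set_size(codons) == size

    def test_set_size_rejects_duplicates(self):
        with pytest.raises(ValueError, match="duplicate"):
            codon_set_size(["AAA", "AAA"])


class TestAdmissibility:
    def test_no_constraints_keeps_all(self):
        spec = PositionSpec("x", {"A": 1})
        assert len(admissible_codons(spec)) == 3375

    def test_forbidding_stop_excludes_stop_producers(self):
        spec = PositionSpec("x", {"A": 1}, forbidden={"*"})
        from dcopt.codons import STOP

        pool = admissible_codons(spec)
        assert all(STOP not in dc.amino_acids() for dc in pool)
        assert 0 < len(pool) < 3375

    def test_required_filter_for_single_codon_consumer(self, lov2_problem):
        pos = by_label(lov2_problem)["413"]  # requires K
        pool = admissible_codons(pos, require_full_coverage=True)
        names = {dc.iupac for dc in pool}
        assert "RMA" in names
        assert all("K" in dc.amino_acids() for dc in pool)

    def test_everything_forbidden_is_infeasible(self):
        spec = PositionSpec("x", {}, forbidden=set("ACDEFGHIKLMNPQRSTVWY*"))
        with pytest.raises(InfeasiblePositionError, match="'x'"):
            admissible_codons(spec)


class TestCoverageClasses:
    def test_single_counted_symbol_gives_two_classes(self):
        spec = PositionSpec("x", {"W": 4})
        reps = coverage_class_representatives(spec)
        assert len(reps) == 2  # W covered / not covered

    def test_real_positions_reduce_to_a_few_hundred(self, surface_problem):
        for p in surface_problem.positions:
            n = len(coverage_class_representatives(p))
            assert 2 <= n <= 450  # orders of magnitude below the 3375 universe

    def test_representatives_are_smallest_per_class(self):
        spec = PositionSpec("x", {"M": 2})
        reps = {dc.iupac for dc in coverage_class_representatives(spec)}
        assert "ATG" in reps  # the unique methionine codon, degeneracy 1


class TestPositionTable:
    def test_published_interface_entry(self, surface_problem):
        table = build_position_table(by_label(surface_problem)["271"], 1)
        entry = table.entry(1, 6)
        assert entry is not None and entry.size == 2

    def test_single_codon_layer_matches_direct_scan(self, surface_problem):
        spec = by_label(surface_problem)["272"]
        table = build_position_table(spec, 1)
        best: dict[int, int] = {}
        for dc in admissible_codons(spec):
            e = codon_error(spec, dc)
            best[e] = min(best.get(e, 1 << 30), dc.degeneracy)
        assert {e: ent.size for e, ent in table.entries[1].items()} == best

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_pairs_match_brute_force_on_restricted_candidates(self, seed):
        spec = PositionSpec("x", {"C": 4, "W": 2, "Y": 1})
        candidates = sample_candidates(seed, 40)
        ours = build_position_table(spec, 2, candidates=candidates)
        ref = brute_force_position_table(spec, 2, candidates=candidates)
        assert ours.entries == ref.entries

    def test_required_union_condition_with_brute_force(self):
        spec = PositionSpec("x", {"C": 4, "V": 2}, required={"V"})
        candidates = sample_candidates(7, 40)
        ours = build_position_table(spec, 2, candidates=candidates)
        ref = brute_force_position_table(spec, 2, candidates=candidates)
        assert ours.entries == ref.entries

    def test_reduction_invariance(self):
        spec = PositionSpec("x", {"A": 3, "S": 2, "G": 1})
        candidates = sample_candidates(11, 60)
        with_red = build_position_table(spec, 2, True, candidates)
        without = build_position_table(spec, 2, False, candidates)
        assert with_red.entries == without.entries

    def test_witnesses_recompute_to_their_cell(self, lov2_problem):
        for p in list(lov2_problem.positions)[:4]:
            table = build_position_table(p, 2)
            for j, by_e in table.entries.items():
                for e, ent in by_e.items():
                    assert len(ent.codons) == j
                    assert codon_set_error(p, ent.codons) == e
                    assert codon_set_size(ent.codons) == ent.size

    def test_more_codons_never_hurt_at_equal_error(self, lov2_problem):
        # With one extra codon allowed, the minimum over j' <= 2 at any error
        # achieved by a single codon is no larger than the single-codon size.
        p = by_label(lov2_problem)["529"]
        table = build_position_table(p, 2)
        for e, ent in table.entries[1].items():
            sizes = [
                t.size
                for j in (1, 2)
                for err, t in table.entries.get(j, {}).items()
                if err == e
            ]
            assert min(sizes) <= ent.size

    def test_infeasible_required_reported_with_label(self):
        # No stop-free single codon produces C, W and Y together; the set
        # only becomes designable with two codons (e.g. TRT + TGG).
        spec = PositionSpec(
            "pX", {"C": 1}, required={"C", "W", "Y"}, forbidden={"*"}
        )
        with pytest.raises(InfeasiblePositionError, match="pX"):
            build_position_table(spec, 1)
        table = build_position_table(spec, 2)
        assert table.entry(2, 0).size == 3
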