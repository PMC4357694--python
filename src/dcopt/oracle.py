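"""Brute-force reference implementations.

These enumerate codon sets and assignments exhaustively and exist solely as
independent oracles for the dynamic programs on small instances; a budget
guard refuses anything that would take combinatorially long.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Sequence

from .codons import DegenerateCodon, as_codon
from .errors import BudgetExceededError, InfeasibleLibraryError
from .library import (
    Limits,
    LibrarySolution,
    PositionAssignment,
    PrimerLimits,
    StretchLayout,
)
from .positions import (
    PositionSpec,
    PositionTable,
    TableEntry,
    admissible_codons,
    codon_set_error,
    codon_set_size,
)


@dataclass(frozen=True)
class OracleBudget:
    max_positions: int = 6
    max_set_size: int = 3
    max_candidates: int = 400
    max_enumerations: int = 2_000_000


DEFAULT_BUDGET = OracleBudget()


def _subset_count(n_candidates: int, max_set: int) -> int:
    return sum(comb(n_candidates, j) for j in range(1, max_set + 1))


def brute_force_position_table(
    spec: PositionSpec,
    max_codons: int,
    candidates: Sequence[DegenerateCodon | str] | None = None,
    budget: OracleBudget = DEFAULT_BUDGET,
) -> PositionTable:
    """Exhaustive minimization over all codon sets of size <= ``max_codons``."""
    pool = sorted(
        dc.iupac for dc in admissible_codons(spec, universe=candidates)
    )
    if max_codons > budget.max_set_size or len(pool) > budget.max_candidates:
        raise BudgetExceededError(
            f"{len(pool)} candidates with sets up to {max_codons} exceeds the budget"
        )
    if _subset_count(len(pool), max_codons) > budget.max_enumerations:
        raise BudgetExceededError("too many codon subsets to enumerate")
    required = spec.required_bits()
    from .codons import universe_tables

    _, degs, aa_bits = universe_tables()
    entries: dict[int, dict[int, TableEntry]] = {}
    for j in range(1, max_codons + 1):
        by_e: dict[int, TableEntry] = {}
        for combo in itertools.combinations(pool, j):
            union = 0
            size = 0
            for name in combo:
                union |= aa_bits[name]
                size += degs[name]
            if union & required != required:
                continue
            e = spec.error_of_coverage(union & spec.relevant_bits())
            cand = TableEntry(size, combo)
            cur = by_e.get(e)
            if cur is None or cand < cur:
                by_e[e] = cand
        if by_e:
            entries[j] = by_e
    if not entries:
        raise InfeasibleLibraryError(
            f"position {spec.label!r}: no admissible codon set under brute force"
        )
    return PositionTable(label=spec.label, max_codons=max_codons, entries=entries)


def brute_force_optimize(
    positions: Sequence[PositionSpec],
    limits: Limits,
    layout: StretchLayout | None = None,
    primer_limits: PrimerLimits | None = None,
    candidates: Sequence[Sequence[DegenerateCodon | str]] | None = None,
    budget: OracleBudget = DEFAULT_BUDGET,
) -> LibrarySolution:
    """Exact optimum by enumerating every codon-set assignment.

    ``candidates`` gives a per-position candidate codon list (or None for the
    full universe).  Constraints: library size <= L; if ``primer_limits`` is
    given, at most L_p codons per position, per-stretch primer products
    <= L_s and total primers <= L_T (a stretch layout is then mandatory).
    """
    if len(positions) > budget.max_positions:
        raise BudgetExceededError(f"{len(positions)} positions exceeds the budget")
    lp = primer_limits.max_codons_per_position if primer_limits else 1
    if primer_limits and layout is None:
        raise ValueError("primer limits require a stretch layout")

    per_position: list[list[tuple[int, int, tuple[str, ...]]]] = []
    total = 1
    for i, spec in enumerate(positions):
        universe = None if candidates is None else candidates[i]
        pool = sorted(dc.iupac for dc in admissible_codons(spec, universe=universe))
        if len(pool) > budget.max_candidates:
            raise BudgetExceededError(f"{len(pool)} candidates at {spec.label!r}")
        options = []
        required = spec.required_bits()
        from .codons import universe_tables

        _, _, aa_bits = universe_tables()
        for j in range(1, lp + 1):
            for combo in itertools.combinations(pool, j):
                union = 0
                for name in combo:
                    union |= aa_bits[name]
                if union & required != required:
                    continue
                options.append(
                    (codon_set_error(spec, combo), codon_set_size(combo), combo)
                )
        if not options:
            raise InfeasibleLibraryError(
                f"position {spec.label!r} has no admissible codon set"
            )
        per_position.append(options)
        total *= len(options)
        if total > budget.max_enumerations:
            raise BudgetExceededError(f"{total} assignments exceeds the budget")

    stretch_index: dict[str, int] = {}
    if layout is not None:
        for si, stretch in enumerate(layout.stretches):
            for label in stretch:
                stretch_index[label] = si

    best = None  # (error, size, codon tuple-of-tuples)
    L = limits.diversity_limit
    for choice in itertools.product(*per_position):
        err = sum(c[0] for c in choice)
        if best is not None and err > best[0]:
            continue
        size = 1
        for c in choice:
            size *= c[1]
        if size > L:
            continue
        if primer_limits is not None:
            per_stretch = [1] * len(layout.stretches)
            for spec, c in zip(positions, choice):
                per_stretch[stretch_index[spec.label]] *= len(c[2])
            if any(ps > primer_limits.max_primers_per_stretch for ps in per_stretch):
                continue
            if sum(per_stretch) > primer_limits.max_primers_total:
                continue
        key = (err, size, tuple(c[2] for c in choice))
        if best is None or key < best:
            best = key
    if best is None:
        raise InfeasibleLibraryError("no feasible assignment under brute force")

    err, size, sets = best
    assignments = tuple(
        PositionAssignment(
            spec.label, combo, codon_set_error(spec, combo), codon_set_size(combo)
        )
        for spec, combo in zip(positions, sets)
    )
    solution = LibrarySolution(assignments=assignments, error=err, size=size)
    if layout is not None:
        from .library import count_primers

        per_stretch, total_primers = count_primers(solution, layout)
        solution.primers_per_stretch = per_stretch
        solution.primers_total = total_primers
    solution.validate(positions, layout)
    return solution
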