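"""Single-codon-per-position dynamic program.

Inverts the constrained minimization (min error s.t. library size <= L) into
"smallest library size at each total error level": S[i][e] is the minimal
product of codon degeneracies over positions 1..i whose per-position errors
sum to e, built from the per-position tables s_i.  A traceback table records
the error each position contributed so the codon assignment can be recovered
in O(n).

Two modes:

* ``"lazy"`` (default, output-sensitive): the total error is the outermost
  loop and the search stops at the first error level whose minimal size fits
  the diversity limit, so only error levels 0..optimum are ever touched.
* ``"full"``: every error level up to sum(m_i) is populated, yielding the
  complete Pareto front of library size versus error.
"""

from __future__ import annotations

from typing import Literal, Sequence

from .errors import InfeasibleLibraryError
from .library import (
    Limits,
    LibrarySolution,
    ParetoFront,
    PositionAssignment,
    StretchLayout,
    count_primers,
)
from .positions import PositionSpec, PositionTable, build_position_table

Mode = Literal["lazy", "full"]


def optimize_single(
    positions: Sequence[PositionSpec],
    limits: Limits,
    mode: Mode = "lazy",
    tables: Sequence[PositionTable] | None = None,
    use_reduction: bool = True,
    candidates=None,
    layout: StretchLayout | None = None,
) -> tuple[LibrarySolution, ParetoFront]:
    """Minimal-error library with one codon per position and size <= L.

    Returns the optimal solution and the Pareto front over the error levels
    explored.  ``tables`` may supply precomputed position tables (entries at
    one codon per position are used); otherwise they are built here, with the
    per-codon required-symbol filter implied by single-codon semantics.
    """
    if not positions:
        raise ValueError("at least one position is required")
    if tables is None:
        tables = [
            build_position_table(p, 1, use_reduction, candidates) for p in positions
        ]
    n = len(positions)
    s = []
    for p, t in zip(positions, tables):
        by_e = t.entries.get(1)
        if not by_e:
            raise InfeasibleLibraryError(
                f"position {p.label!r} admits no single codon covering its required symbols"
            )
        s.append({e: ent for e, ent in sorted(by_e.items())})

    # Quick global feasibility: even the smallest per-position sizes may
    # multiply out beyond L.
    min_possible = 1
    for by_e in s:
        min_possible *= min(ent.size for ent in by_e.values())
    L = limits.diversity_limit
    if min_possible > L:
        raise InfeasibleLibraryError(
            f"no feasible library: the smallest assignment has size {min_possible} > {L}"
        )

    e_cap = sum(max(by_e) for by_e in s)
    S: list[dict[int, int]] = [{} for _ in range(n)]
    T: list[dict[int, int]] = [{} for _ in range(n)]
    size_by_error: dict[int, int] = {}
    best_error: int | None = None
    for e in range(e_cap + 1):
        for i in range(n):
            if i == 0:
                ent = s[0].get(e)
                if ent is not None:
                    S[0][e] = ent.size
                    T[0][e] = e
                continue
            best = None
            arg = None
            for e_here, ent in s[i].items():  # ascending: smallest e' wins ties
                if e_here > e:
                    break
                prev = S[i - 1].get(e - e_here)
                if prev is None:
                    continue
                cand = prev * ent.size
                if best is None or cand < best:
                    best, arg = cand, e_here
            if best is not None:
                S[i][e] = best
                T[i][e] = arg
        total = S[n - 1].get(e)
        if total is not None:
            size_by_error[e] = total
            if best_error is None and total <= L:
                best_error = e
                if mode == "lazy":
                    break

    if best_error is None:
        raise InfeasibleLibraryError(
            f"no feasible library of size <= {L} at any error level up to {e_cap}"
        )
    solution = traceback_single(T, best_error, s, [p.label for p in positions])
    if layout is not None:
        per_stretch, total = count_primers(solution, layout)
        solution.primers_per_stretch = per_stretch
        solution.primers_total = total
    solution.validate(positions, layout)
    return solution, ParetoFront.from_size_by_error(size_by_error)


def traceback_single(
    T: Sequence[dict[int, int]],
    target_error: int,
    s: Sequence[dict[int, "TableEntry"]],
    labels: Sequence[str],
) -> LibrarySolution:
    """Recover the codon assignment achieving ``target_error`` from T."""
    n = len(labels)
    if target_error not in T[n - 1]:
        raise InfeasibleLibraryError(f"error level {target_error} is not achievable")
    assignments = []
    e = target_error
    for i in range(n - 1, -1, -1):
        e_here = T[i][e]
        ent = s[i][e_here]
        assignments.append(
            PositionAssignment(labels[i], ent.codons, e_here, ent.size)
        )
        e -= e_here
    assignments.reverse()
    size = 1
    for a in assignments:
        size *= a.size
    return LibrarySolution(
        assignments=tuple(assignments), error=target_error, size=size
    )
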