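"""Multi-codon dynamic program with primer accounting over stretches.

Positions are covered by synthesized primers in contiguous *stretches*; using
several degenerate codons at a position multiplies the number of primer
variants the stretch needs (the cartesian product over its positions must be
ordered).  The DP state at position i is (total primers j, primers for i's
stretch k, total error e) and stores the minimal library size.  At the first
position of a stretch the previous stretch's primer count is released
(minimized over) and the new stretch starts with k equal to the number of
codons chosen; within a stretch, choosing j' codons multiplies k by j' and
adds (j'-1) * k_prev primers to the total.  The budgets are L_p codons per
position, L_s primers per stretch and L_T primers overall.

Tables are stored sparsely (dicts keyed by error, then by (j, k)); the
default "lazy" mode iterates total error outermost and stops at the first
feasible level, exactly as in the single-codon program.
"""

from __future__ import annotations

from typing import Sequence

from .dp_single import Mode
from .errors import ConfigError, InfeasibleLibraryError
from .library import (
    Limits,
    LibrarySolution,
    ParetoFront,
    PositionAssignment,
    PrimerLimits,
    StretchLayout,
    count_primers,
)
from .positions import PositionSpec, PositionTable, build_position_table


def optimize_multi(
    positions: Sequence[PositionSpec],
    layout: StretchLayout,
    limits: Limits,
    primer_limits: PrimerLimits,
    mode: Mode = "lazy",
    tables: Sequence[PositionTable] | None = None,
    use_reduction: bool = True,
    candidates=None,
) -> tuple[LibrarySolution, ParetoFront]:
    """Minimal-error library using up to L_p codons per position within the
    primer budgets, with size <= L.

    ``tables`` may be precomputed (possibly at a larger codon-count limit than
    ``primer_limits`` asks for; only entries with at most L_p codons are
    read).  Required symbols are a union condition over each position's set.
    """
    if not positions:
        raise ValueError("at least one position is required")
    labels = [p.label for p in positions]
    layout.validate_against(labels)
    lp = primer_limits.max_codons_per_position
    ls = primer_limits.max_primers_per_stretch
    lt = primer_limits.max_primers_total
    if lt < len(layout.stretches):
        raise ConfigError(
            f"max_primers_total={lt} cannot cover {len(layout.stretches)} stretches "
            "(each needs at least one primer)"
        )
    if tables is None:
        tables = [
            build_position_table(p, lp, use_reduction, candidates) for p in positions
        ]

    n = len(positions)
    # s[i][j'] = {e': TableEntry}, ascending in e'; s_errors[i] = all e' seen.
    s: list[dict[int, dict[int, object]]] = []
    s_errors: list[list[int]] = []
    for p, t in zip(positions, tables):
        by_j = {
            j: dict(sorted(by_e.items()))
            for j, by_e in t.entries.items()
            if j <= lp and by_e
        }
        if not by_j:
            raise InfeasibleLibraryError(
                f"position {p.label!r} admits no codon set of <= {lp} codons"
            )
        s.append(by_j)
        s_errors.append(sorted({e for by_e in by_j.values() for e in by_e}))

    first = layout.first_in_stretch_flags()
    L = limits.diversity_limit
    e_cap = sum(errs[-1] for errs in s_errors)

    # S[i][e] = {(j, k): (size, (e', j', prev_j, prev_k))}
    # M[i][e] = {j: (size, k)}  -- min over k, used at stretch transitions.
    S: list[dict[int, dict[tuple[int, int], tuple[int, tuple]]]] = [
        {} for _ in range(n)
    ]
    M: list[dict[int, dict[int, tuple[int, int]]]] = [{} for _ in range(n)]
    size_by_error: dict[int, int] = {}
    best_error: int | None = None

    for e in range(e_cap + 1):
        for i in range(n):
            row: dict[tuple[int, int], tuple[int, tuple]] = {}
            if i == 0:
                for jp in range(1, min(lp, ls, lt) + 1):
                    ent = s[0].get(jp, {}).get(e)
                    if ent is not None:
                        row[(jp, jp)] = (ent.size, (e, jp, None, None))
            elif first[i]:
                for e_here in s_errors[i]:
                    if e_here > e:
                        break
                    prev_m = M[i - 1].get(e - e_here)
                    if not prev_m:
                        continue
                    for jp in range(1, min(lp, ls) + 1):
                        ent = s[i].get(jp, {}).get(e_here)
                        if ent is None:
                            continue
                        for j_prev in sorted(prev_m):
                            psize, pk = prev_m[j_prev]
                            j = j_prev + jp
                            if j > lt:
                                continue
                            cand = psize * ent.size
                            st = (j, jp)
                            if st not in row or cand < row[st][0]:
                                row[st] = (cand, (e_here, jp, j_prev, pk))
            else:
                for e_here in s_errors[i]:
                    if e_here > e:
                        break
                    prev_row = S[i - 1].get(e - e_here)
                    if not prev_row:
                        continue
                    for jp in range(1, min(lp, ls, lt) + 1):
                        ent = s[i].get(jp, {}).get(e_here)
                        if ent is None:
                            continue
                        for (pj, pk) in sorted(prev_row):
                            k = pk * jp
                            if k > ls:
                                continue
                            j = pj + (jp - 1) * pk
                            if j > lt:
                                continue
                            cand = prev_row[(pj, pk)][0] * ent.size
                            st = (j, k)
                            if st not in row or cand < row[st][0]:
                                row[st] = (cand, (e_here, jp, pj, pk))
            if row:
                S[i][e] = row
                m_row: dict[int, tuple[int, int]] = {}
                for (j, k) in sorted(row):
                    sz = row[(j, k)][0]
                    if j not in m_row or sz < m_row[j][0]:
                        m_row[j] = (sz, k)
                M[i][e] = m_row
        last = S[n - 1].get(e)
        if last:
            size_by_error[e] = min(v[0] for v in last.values())
            if best_error is None and any(v[0] <= L for v in last.values()):
                best_error = e
                if mode == "lazy":
                    break

    if best_error is None:
        raise InfeasibleLibraryError(
            f"no library satisfies size <= {L} with primer limits "
            f"(L_p={lp}, L_s={ls}, L_T={lt}) at any error level up to {e_cap}"
        )

    solution = _traceback_multi(S, s, labels, best_error, L)
    per_stretch, total = count_primers(solution, layout)
    if any(ps > ls for ps in per_stretch) or total > lt:  # pragma: no cover
        raise AssertionError("primer accounting violated its own limits")
    solution.primers_per_stretch = per_stretch
    solution.primers_total = total
    solution.validate(positions, layout)
    return solution, ParetoFront.from_size_by_error(size_by_error)


def _traceback_multi(S, s, labels, target_error: int, diversity_limit: int):
    n = len(labels)
    last = S[n - 1][target_error]
    feasible = sorted(
        (sz, st) for st, (sz, _) in last.items() if sz <= diversity_limit
    )
    size, state = feasible[0]
    assignments = []
    e = target_error
    for i in range(n - 1, -1, -1):
        _, tb = S[i][e][state]
        e_here, jp, pj, pk = tb
        ent = s[i][jp][e_here]
        assignments.append(
            PositionAssignment(labels[i], ent.codons, e_here, ent.size)
        )
        e -= e_here
        state = (pj, pk)
    assignments.reverse()
    return LibrarySolution(
        assignments=tuple(assignments), error=target_error, size=size
    )
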