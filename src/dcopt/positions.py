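"""Per-position error model and partial-solution tables.

A randomized position is described by integer amino-acid counts C_i(a) (how
often each symbol was observed in the input designs), optional integer
penalties for symbols better left out, and required/forbidden symbols.  The
error of a codon set at the position is the summed count of observed symbols
its union misses, plus the summed penalty of penalized symbols it hits.
Because every term is integral, the downstream dynamic programs can index
their tables by error.

``build_position_table`` computes, for each codon-set cardinality j' up to a
limit and every achievable error e', the smallest combined DNA size over sets
of exactly j' distinct codons whose union covers all required symbols,
together with one witness set.  The search runs over coverage-class
representatives: codons are grouped by which error-relevant symbols they
cover, and only the few smallest codons per class can ever appear in an
optimal set, which shrinks the candidate list from 3375 to a few hundred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from .codons import (
    DegenerateCodon,
    SYMBOL_INDEX,
    as_codon,
    symbols_to_bits,
    universe_tables,
)
from .errors import InfeasiblePositionError


def _validate_symbol_map(name: str, mapping: Mapping[str, int]) -> dict[str, int]:
    out = {}
    for sym, v in mapping.items():
        if sym not in SYMBOL_INDEX:
            raise ValueError(f"{name} has unknown symbol {sym!r}")
        if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
            raise ValueError(f"{name}[{sym!r}] must be a non-negative integer, got {v!r}")
        out[sym] = int(v)
    return out


@dataclass
class PositionSpec:
    """One randomized position: counts, penalties, required/forbidden symbols."""

    label: str
    counts: Mapping[str, int]
    penalties: Mapping[str, int] = field(default_factory=dict)
    required: frozenset[str] = frozenset()
    forbidden: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.counts = _validate_symbol_map("counts", self.counts)
        self.penalties = _validate_symbol_map("penalties", self.penalties)
        self.required = frozenset(self.required)
        self.forbidden = frozenset(self.forbidden)
        for name, group in (("required", self.required), ("forbidden", self.forbidden)):
            bad = group - set(SYMBOL_INDEX)
            if bad:
                raise ValueError(f"{name} has unknown symbols {sorted(bad)}")
        overlap = self.required & self.forbidden
        if overlap:
            raise ValueError(
                f"position {self.label!r}: symbols {sorted(overlap)} both required and forbidden"
            )
        counted_forbidden = {s for s in self.forbidden if self.counts.get(s, 0) > 0}
        if counted_forbidden:
            raise ValueError(
                f"position {self.label!r}: positively counted symbols "
                f"{sorted(counted_forbidden)} may not be forbidden"
            )

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def desired_symbols(self) -> frozenset[str]:
        """Symbols with a positive count (the 'desired' amino acids)."""
        return frozenset(s for s, c in self.counts.items() if c > 0)

    # -- integer views ------------------------------------------------------

    def relevant_bits(self) -> int:
        """Bitmask of error-relevant symbols: counted, penalized or required."""
        bits = symbols_to_bits(self.desired_symbols())
        bits |= symbols_to_bits(s for s, p in self.penalties.items() if p > 0)
        bits |= symbols_to_bits(self.required)
        return bits

    def required_bits(self) -> int:
        return symbols_to_bits(self.required)

    def forbidden_bits(self) -> int:
        return symbols_to_bits(self.forbidden)

    def error_of_coverage(self, covered_bits: int) -> int:
        """Error of any codon set whose union covers exactly ``covered_bits``."""
        err = 0
        for sym, c in self.counts.items():
            if c > 0 and not covered_bits >> SYMBOL_INDEX[sym] & 1:
                err += c
        for sym, p in self.penalties.items():
            if p > 0 and covered_bits >> SYMBOL_INDEX[sym] & 1:
                err += p
        return err


def codon_error(spec: PositionSpec, dc: DegenerateCodon | str) -> int:
    """Error of a single codon: counts it misses plus penalties it hits."""
    _, _, aa_bits = universe_tables()
    return spec.error_of_coverage(aa_bits[as_codon(dc).iupac])


def codon_set_error(spec: PositionSpec, codons: Iterable[DegenerateCodon | str]) -> int:
    """Error of a codon set, judged on the union of its members' symbol sets."""
    _, _, aa_bits = universe_tables()
    union = 0
    n = 0
    for dc in codons:
        union |= aa_bits[as_codon(dc).iupac]
        n += 1
    if n == 0:
        raise ValueError("codon set must be non-empty")
    return spec.error_of_coverage(union)


def codon_set_size(codons: Iterable[DegenerateCodon | str]) -> int:
    """Combined DNA size of a codon set: the sum of member degeneracies."""
    names = [as_codon(dc).iupac for dc in codons]
    if not names:
        raise ValueError("codon set must be non-empty")
    if len(set(names)) != len(names):
        raise ValueError(f"codon set has duplicate members: {sorted(names)}")
    _, degs, _ = universe_tables()
    return sum(degs[s] for s in names)


def admissible_codons(
    spec: PositionSpec,
    universe: Sequence[DegenerateCodon | str] | None = None,
    require_full_coverage: bool = False,
) -> list[DegenerateCodon]:
    """Codons producing no forbidden symbol.

    With ``require_full_coverage`` (the single-codon consumer) each codon must
    by itself cover every required symbol; multi-codon tables instead apply
    the required-coverage condition to the union of the chosen set.
    """
    iupacs, _, aa_bits = universe_tables()
    names = iupacs if universe is None else [as_codon(d).iupac for d in universe]
    fb = spec.forbidden_bits()
    req = spec.required_bits()
    out = []
    for s in names:
        bits = aa_bits[s]
        if bits & fb:
            continue
        if require_full_coverage and bits & req != req:
            continue
        out.append(as_codon(s))
    if not out:
        raise InfeasiblePositionError(spec.label)
    return out


def coverage_class_representatives(
    spec: PositionSpec,
    codons: Sequence[DegenerateCodon | str] | None = None,
    per_class: int = 1,
) -> list[DegenerateCodon]:
    """One (or ``per_class``) smallest codon(s) per distinct coverage of
    error-relevant symbols.

    Two codons covering the same subset of counted/penalized/required symbols
    are interchangeable up to size, so only the smallest members of each class
    can appear in an optimal codon set; keeping ``per_class`` = L_p of them
    preserves optima even for sets of exactly L_p codons (a set never needs
    more members from one class than its own cardinality).
    """
    if codons is None:
        codons = admissible_codons(spec)
    _, degs, aa_bits = universe_tables()
    relevant = spec.relevant_bits()
    classes: dict[int, list[str]] = {}
    for dc in codons:
        s = as_codon(dc).iupac
        classes.setdefault(aa_bits[s] & relevant, []).append(s)
    reps: list[str] = []
    for sig in sorted(classes):
        members = sorted(classes[sig], key=lambda s: (degs[s], s))
        reps.extend(members[:per_class])
    return [as_codon(s) for s in sorted(reps)]


class TableEntry(NamedTuple):
    size: int
    codons: tuple[str, ...]


@dataclass
class PositionTable:
    """Smallest-library sizes for one position, indexed by (#codons j', error e').

    ``entries[j'][e']`` holds the minimal combined DNA size over sets of
    exactly j' distinct admissible codons with union error e' and full
    required coverage, plus one witness set; absent keys are infeasible.
    """

    label: str
    max_codons: int
    entries: dict[int, dict[int, TableEntry]]

    @property
    def max_error(self) -> int:
        """m_i: the largest finite error stored at this position."""
        return max(
            (e for by_e in self.entries.values() for e in by_e), default=0
        )

    def entry(self, n_codons: int, error: int) -> TableEntry | None:
        return self.entries.get(n_codons, {}).get(error)

    def errors_at(self, n_codons: int) -> list[int]:
        return sorted(self.entries.get(n_codons, {}))

    def achievable_errors(self) -> list[int]:
        return sorted({e for by_e in self.entries.values() for e in by_e})


def build_position_table(
    spec: PositionSpec,
    max_codons: int = 1,
    use_reduction: bool = True,
    candidates: Sequence[DegenerateCodon | str] | None = None,
) -> PositionTable:
    """Build the per-position table s_i for codon sets of size 1..``max_codons``.

    ``candidates`` restricts the codon universe (used by tests to keep
    brute-force comparisons tractable); by default all 3375 codons are
    considered.  ``use_reduction`` enables the coverage-class preprocessing;
    tables are identical either way.
    """
    if max_codons < 1:
        raise ValueError(f"max_codons must be >= 1, got {max_codons}")
    pool = admissible_codons(spec, universe=candidates)
    if use_reduction:
        pool = coverage_class_representatives(spec, pool, per_class=max_codons)
    _, degs, aa_bits = universe_tables()
    relevant = spec.relevant_bits()
    required = spec.required_bits()

    # 0/1-knapsack over the candidate codons: layer j maps each achievable
    # coverage signature to the smallest set of exactly j distinct codons
    # producing it.  Processing layers top-down per codon guarantees no codon
    # is used twice.
    empty = TableEntry(0, ())
    layers: list[dict[int, TableEntry]] = [{0: empty}] + [
        {} for _ in range(max_codons)
    ]
    ordered = sorted((as_codon(d).iupac for d in pool))
    for name in ordered:
        sig = aa_bits[name] & relevant
        deg = degs[name]
        for j in range(max_codons - 1, -1, -1):
            for prev_sig, prev in layers[j].items():
                new_sig = prev_sig | sig
                cand = TableEntry(
                    prev.size + deg, tuple(sorted(prev.codons + (name,)))
                )
                cur = layers[j + 1].get(new_sig)
                if cur is None or cand < cur:
                    layers[j + 1][new_sig] = cand

    entries: dict[int, dict[int, TableEntry]] = {}
    err_cache: dict[int, int] = {}
    for j in range(1, max_codons + 1):
        by_e: dict[int, TableEntry] = {}
        for sig, ent in layers[j].items():
            if sig & required != required:
                continue
            e = err_cache.get(sig)
            if e is None:
                e = err_cache[sig] = spec.error_of_coverage(sig)
            cur = by_e.get(e)
            if cur is None or ent < cur:
                by_e[e] = ent
        if by_e:
            entries[j] = by_e
    if not entries:
        raise InfeasiblePositionError(
            spec.label,
            f"position {spec.label!r}: no admissible codon set of <= "
            f"{max_codons} codons covers the required symbols",
        )
    return PositionTable(label=spec.label, max_codons=max_codons, entries=entries)
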