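"""Shared containers: limits, stretch layout, library solutions, Pareto front."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

from .errors import ConfigError
from .positions import PositionSpec, codon_set_error, codon_set_size


@dataclass(frozen=True)
class Limits:
    """The diversity limit L: the most DNA sequences the library may define."""

    diversity_limit: int

    def __post_init__(self) -> None:
        if not isinstance(self.diversity_limit, int) or self.diversity_limit < 1:
            raise ConfigError(
                f"diversity_limit must be a positive integer, got {self.diversity_limit!r}"
            )


@dataclass(frozen=True)
class PrimerLimits:
    """Primer budgets: codons per position L_p, primers per stretch L_s, total L_T."""

    max_codons_per_position: int
    max_primers_per_stretch: int | None = None
    max_primers_total: int | None = None

    def __post_init__(self) -> None:
        lp = self.max_codons_per_position
        lt = self.max_primers_total if self.max_primers_total is not None else lp
        # An unspecified per-stretch limit defaults to the total limit.
        ls = self.max_primers_per_stretch if self.max_primers_per_stretch is not None else lt
        for name, v in (
            ("max_codons_per_position", lp),
            ("max_primers_per_stretch", ls),
            ("max_primers_total", lt),
        ):
            if not isinstance(v, int) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if not lp <= ls <= lt:
            raise ConfigError(
                "primer limits must satisfy max_codons_per_position <= "
                f"max_primers_per_stretch <= max_primers_total, got {lp} <= {ls} <= {lt}"
            )
        object.__setattr__(self, "max_primers_per_stretch", ls)
        object.__setattr__(self, "max_primers_total", lt)


@dataclass(frozen=True)
class StretchLayout:
    """Ordered partition of the designable positions into primer stretches."""

    stretches: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        stretches = tuple(tuple(str(p) for p in s) for s in self.stretches)
        if not stretches or any(not s for s in stretches):
            raise ConfigError("every stretch must contain at least one position")
        flat = [p for s in stretches for p in s]
        if len(set(flat)) != len(flat):
            raise ConfigError("a position may appear in only one stretch")
        object.__setattr__(self, "stretches", stretches)

    @classmethod
    def single_stretch(cls, labels: Iterable[str]) -> "StretchLayout":
        return cls((tuple(labels),))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p for s in self.stretches for p in s)

    def first_in_stretch_flags(self) -> list[bool]:
        flags = []
        for s in self.stretches:
            flags.extend([True] + [False] * (len(s) - 1))
        return flags

    def validate_against(self, labels: Sequence[str]) -> None:
        if self.labels != tuple(labels):
            raise ConfigError(
                "stretch layout does not list the positions in their table order: "
                f"layout gives {self.labels}, positions are {tuple(labels)}"
            )


@dataclass(frozen=True)
class PositionAssignment:
    """The codon set chosen at one position, with its error and DNA size."""

    label: str
    codons: tuple[str, ...]
    error: int
    size: int


@dataclass
class LibrarySolution:
    """A full codon assignment: per-position codon sets, total error and size."""

    assignments: tuple[PositionAssignment, ...]
    error: int
    size: int
    primers_per_stretch: tuple[int, ...] | None = None
    primers_total: int | None = None

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(a.label for a in self.assignments)

    def codon_sets(self) -> dict[str, tuple[str, ...]]:
        return {a.label: a.codons for a in self.assignments}

    def recompute(self, positions: Sequence[PositionSpec]) -> tuple[int, int]:
        """(total error, total size) re-evaluated from the codon sets."""
        by_label = {p.label: p for p in positions}
        err, size = 0, 1
        for a in self.assignments:
            err += codon_set_error(by_label[a.label], a.codons)
            size *= codon_set_size(a.codons)
        return err, size

    def validate(
        self,
        positions: Sequence[PositionSpec],
        layout: StretchLayout | None = None,
    ) -> None:
        """Assert the stored error/size/primer counts match a recomputation."""
        err, size = self.recompute(positions)
        if (err, size) != (self.error, self.size):
            raise AssertionError(
                f"solution inconsistent: stored (error={self.error}, size={self.size}) "
                f"!= recomputed ({err}, {size})"
            )
        if layout is not None and self.primers_total is not None:
            per_stretch, total = count_primers(self, layout)
            if (per_stretch, total) != (self.primers_per_stretch, self.primers_total):
                raise AssertionError(
                    f"primer counts inconsistent: stored {self.primers_per_stretch} "
                    f"(total {self.primers_total}) != recomputed {per_stretch} ({total})"
                )


def count_primers(
    solution: LibrarySolution, layout: StretchLayout
) -> tuple[tuple[int, ...], int]:
    """Primers per stretch (product of codon counts at its positions) and total."""
    sets = solution.codon_sets()
    missing = set(layout.labels) - set(sets)
    if missing:
        raise ConfigError(f"solution lacks positions {sorted(missing)} named by the layout")
    per_stretch = []
    for stretch in layout.stretches:
        n = 1
        for label in stretch:
            n *= len(sets[label])
        per_stretch.append(n)
    return tuple(per_stretch), sum(per_stretch)


class ParetoPoint(NamedTuple):
    error: int
    size: int


class ParetoFront:
    """Non-dominated (error, minimal size) points, error ascending."""

    def __init__(self, points: Iterable[ParetoPoint]):
        pts = sorted(points)
        pruned: list[ParetoPoint] = []
        best = None
        for p in pts:
            if best is None or p.size < best:
                pruned.append(ParetoPoint(*p))
                best = p.size
        self.points: tuple[ParetoPoint, ...] = tuple(pruned)

    @classmethod
    def from_size_by_error(cls, size_by_error: Mapping[int, int]) -> "ParetoFront":
        return cls(ParetoPoint(e, s) for e, s in size_by_error.items())

    def __iter__(self) -> Iterator[ParetoPoint]:
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def min_error_under(self, diversity_limit: int) -> int | None:
        """Smallest error whose minimal size fits the limit, if on the front."""
        for p in self.points:
            if p.size <= diversity_limit:
                return p.error
        return None
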