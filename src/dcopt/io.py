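"""Counts-table and configuration readers/writers.

A counts table is a TSV/CSV with one header row of position labels, one row
per amino-acid symbol (the 20 one-letter codes plus an optional ``*`` row for
stop) and non-negative integer cells; each column becomes a
:class:`~dcopt.positions.PositionSpec`, in column order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .codons import SYMBOL_INDEX
from .errors import ConfigError, CountsTableError
from .library import PrimerLimits, StretchLayout
from .positions import PositionSpec


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise CountsTableError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
        return "\t" if dialect == "tsv" else ","
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts_table(
    path: str | Path, dialect: str | None = None
) -> list[PositionSpec]:
    """Read a counts table into one PositionSpec per column."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep), None)
    if not header or len(header) < 2:
        raise CountsTableError(f"{path}: empty or header-less counts table")
    labels = [str(c) for c in header[1:]]
    if len(set(labels)) != len(labels):
        dupes = sorted({c for c in labels if labels.count(c) > 1})
        raise CountsTableError(f"{path}: duplicate position labels {dupes}")

    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str).fillna("0")
    symbols = [str(s) for s in frame.index]
    if len(set(symbols)) != len(symbols):
        dupes = sorted({s for s in symbols if symbols.count(s) > 1})
        raise CountsTableError(f"{path}: duplicate symbol rows {dupes}")
    unknown = [s for s in symbols if s not in SYMBOL_INDEX]
    if unknown:
        raise CountsTableError(f"{path}: unknown symbol rows {unknown}")
    if frame.empty:
        raise CountsTableError(f"{path}: counts table has no symbol rows")

    specs = []
    for label in labels:
        counts = {}
        for sym in symbols:
            raw = str(frame.at[sym, label]).strip()
            try:
                v = int(raw)
            except ValueError:
                raise CountsTableError(
                    f"{path}: non-integer count {raw!r} at symbol {sym!r}, "
                    f"position {label!r}"
                ) from None
            if v < 0:
                raise CountsTableError(
                    f"{path}: negative count {v} at symbol {sym!r}, position {label!r}"
                )
            counts[sym] = v
        specs.append(PositionSpec(label=label, counts=counts))
    return specs


def write_counts_table(
    specs: Sequence[PositionSpec], path: str | Path, dialect: str | None = None
) -> None:
    path = Path(path)
    sep = _sep_for(path, dialect)
    symbols = [s for s in SYMBOL_INDEX if any(p.counts.get(s, 0) > 0 for p in specs)]
    symbols = symbols or ["A"]
    frame = pd.DataFrame(
        {p.label: [p.counts.get(s, 0) for s in symbols] for p in specs},
        index=pd.Index(symbols, name="aa"),
    )
    frame.to_csv(path, sep=sep)


def parse_diversity_limit(text: str | int) -> int:
    """Parse a diversity limit, accepting scientific notation ('3.2e8'),
    flooring to an exact integer."""
    if isinstance(text, int):
        value = Decimal(text)
    else:
        try:
            value = Decimal(str(text))
        except Exception:
            raise ConfigError(f"diversity limit {text!r} is not a number") from None
    n = int(value)  # truncates toward zero; limits are positive
    if n < 1:
        raise ConfigError(f"diversity limit must be >= 1, got {text!r}")
    return n


def parse_stretches(text: str) -> StretchLayout:
    """Parse a CLI stretch spec: groups separated by '/', labels by ','.

    Example: ``268,269,270,271,272,276/330,331,332``.
    """
    groups = [g for g in text.split("/") if g.strip()]
    if not groups:
        raise ConfigError(f"empty stretch specification {text!r}")
    return StretchLayout(
        tuple(tuple(lbl.strip() for lbl in g.split(",") if lbl.strip()) for g in groups)
    )


def parse_symbol_assignments(text: str) -> dict[str, frozenset[str]]:
    """Parse per-position symbol lists: ``413:K;475:EQ`` -> {label: symbols}."""
    out: dict[str, frozenset[str]] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            raise ConfigError(f"expected 'label:SYMBOLS', got {part!r}")
        label, syms = part.split(":", 1)
        symbols = frozenset(syms.strip())
        bad = symbols - set(SYMBOL_INDEX)
        if bad:
            raise ConfigError(f"unknown symbols {sorted(bad)} for position {label!r}")
        out[label.strip()] = symbols
    return out


@dataclass
class RunConfig:
    """A validated optimization run: counts file plus constraints."""

    counts: str
    diversity_limit: int
    stretches: StretchLayout | None = None
    max_codons_per_position: int = 1
    max_primers_per_stretch: int | None = None
    max_primers_total: int | None = None
    penalties: Mapping[str, int] = field(default_factory=dict)
    required: Mapping[str, frozenset[str]] = field(default_factory=dict)
    forbidden: Mapping[str, frozenset[str]] = field(default_factory=dict)
    mode: str = "lazy"

    def __post_init__(self) -> None:
        if self.mode not in ("lazy", "full"):
            raise ConfigError(f"mode must be 'lazy' or 'full', got {self.mode!r}")
        self.diversity_limit = parse_diversity_limit(self.diversity_limit)
        # Delegates range/ordering checks to PrimerLimits.
        self.primer_limits  # noqa: B018

    @property
    def primer_limits(self) -> PrimerLimits:
        return PrimerLimits(
            self.max_codons_per_position,
            self.max_primers_per_stretch,
            self.max_primers_total,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: configuration must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise ConfigError(f"{path}: unknown configuration fields {sorted(extra)}")
        if "stretches" in raw and raw["stretches"] is not None:
            raw["stretches"] = StretchLayout(
                tuple(tuple(str(p) for p in s) for s in raw["stretches"])
            )
        for field_name in ("required", "forbidden"):
            if field_name in raw and raw[field_name] is not None:
                raw[field_name] = {
                    str(k): frozenset(v) for k, v in raw[field_name].items()
                }
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from None

    def build_positions(self) -> list[PositionSpec]:
        specs = read_counts_table(self.counts)
        return [
            PositionSpec(
                label=p.label,
                counts=p.counts,
                penalties=dict(self.penalties),
                required=self.required.get(p.label, frozenset()),
                forbidden=self.forbidden.get(p.label, frozenset()),
            )
            for p in specs
        ]
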