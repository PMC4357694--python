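"""Library summary statistics.

For each position the report gives the chosen codon set, the amino acids it
produces, the DNA count (#NA: expanded codons, with multiplicity across the
set), the distinct amino-acid count (#AA: stop excluded) and the percentage
of the expanded codons that translate to a *desired* amino acid — one with a
positive observation count at that position.  Library totals multiply the
per-position values: DNA size, amino-acid sequence count, the percentage of
library members containing only desired amino acids, the total error and the
AA:DNA ratio (1 means the genetic code's redundancy is fully side-stepped).

Percentages are exact rationals internally; rounding (nearest integer per
position, one decimal for totals) happens only at render time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .codons import STOP, as_codon
from .library import LibrarySolution, ParetoFront
from .positions import PositionSpec, codon_set_error


@dataclass(frozen=True)
class PositionReport:
    label: str
    codons: tuple[str, ...]
    amino_acids: str
    dna_count: int
    aa_count: int
    desired_fraction: Fraction
    error: int


@dataclass(frozen=True)
class LibraryReport:
    rows: tuple[PositionReport, ...]
    dna_size: int
    aa_sequences: int
    desired_fraction: Fraction
    error: int

    @property
    def aa_dna_ratio(self) -> Fraction:
        return Fraction(self.aa_sequences, self.dna_size)

    @property
    def percent_desired(self) -> float:
        """Library members made only of desired amino acids, in percent,
        rounded to one decimal."""
        return round(float(100 * self.desired_fraction), 1)


def summarize(
    solution: LibrarySolution, positions: Sequence[PositionSpec]
) -> LibraryReport:
    by_label = {p.label: p for p in positions}
    missing = set(solution.labels) - set(by_label)
    if missing:
        raise ValueError(f"no PositionSpec for positions {sorted(missing)}")
    rows = []
    dna_size = 1
    aa_sequences = 1
    desired_total = Fraction(1)
    error = 0
    for a in solution.assignments:
        spec = by_label[a.label]
        desired = spec.desired_symbols()
        union: set[str] = set()
        n_dna = 0
        n_desired = 0
        for name in a.codons:
            dc = as_codon(name)
            for plain in dc.expand():
                n_dna += 1
                sym = _translate(plain)
                union.add(sym)
                if sym in desired:
                    n_desired += 1
        n_aa = len(union - {STOP})
        frac = Fraction(n_desired, n_dna)
        err = codon_set_error(spec, a.codons)
        rows.append(
            PositionReport(
                label=a.label,
                codons=a.codons,
                amino_acids="".join(sorted(union)),
                dna_count=n_dna,
                aa_count=n_aa,
                desired_fraction=frac,
                error=err,
            )
        )
        dna_size *= n_dna
        aa_sequences *= n_aa
        desired_total *= frac
        error += err
    return LibraryReport(
        rows=tuple(rows),
        dna_size=dna_size,
        aa_sequences=aa_sequences,
        desired_fraction=desired_total,
        error=error,
    )


def _translate(plain_codon: str) -> str:
    from .codons import STANDARD_CODE

    return STANDARD_CODE.translate(plain_codon)


def format_size(n: int) -> str:
    """Decimal, plus 2-significant-figure scientific notation from 10^6 up."""
    if n >= 10**6:
        return f"{n:.1e}"
    return str(n)


def render_tsv(report: LibraryReport) -> str:
    """Human-readable TSV mirroring the per-position solution-table layout."""
    labels = [r.label for r in report.rows]
    lines = [
        "\t".join(["row"] + labels + ["Totals"]),
        "\t".join(["DCs"] + [",".join(r.codons) for r in report.rows] + [""]),
        "\t".join(["AAs"] + [r.amino_acids for r in report.rows] + [""]),
        "\t".join(
            ["#NAs"]
            + [str(r.dna_count) for r in report.rows]
            + [format_size(report.dna_size)]
        ),
        "\t".join(
            ["#AAs"]
            + [str(r.aa_count) for r in report.rows]
            + [format_size(report.aa_sequences)]
        ),
        "\t".join(
            ["%Des"]
            + [str(round(float(100 * r.desired_fraction))) for r in report.rows]
            + [f"{report.percent_desired:.1f}"]
        ),
        "\t".join(
            ["Error"] + [str(r.error) for r in report.rows] + [str(report.error)]
        ),
    ]
    return "\n".join(lines) + "\n"


def solution_to_dict(
    solution: LibrarySolution, report: LibraryReport | None = None
) -> dict:
    """JSON-ready view; sizes serialized as decimal strings (they routinely
    exceed 53-bit float precision)."""
    out = {
        "positions": [
            {
                "label": a.label,
                "codons": list(a.codons),
                "error": a.error,
                "size": str(a.size),
            }
            for a in solution.assignments
        ],
        "error": solution.error,
        "size": str(solution.size),
    }
    if solution.primers_total is not None:
        out["primers_per_stretch"] = list(solution.primers_per_stretch)
        out["primers_total"] = solution.primers_total
    if report is not None:
        out["aa_sequences"] = str(report.aa_sequences)
        out["percent_desired"] = report.percent_desired
        out["aa_dna_ratio"] = float(report.aa_dna_ratio)
    return out


def render_pareto_tsv(front: ParetoFront) -> str:
    """(error, minimal size, log10 size) rows for plotting."""
    import math

    lines = ["error\tmin_size\tlog10_size"]
    for p in front:
        lines.append(f"{p.error}\t{p.size}\t{math.log10(p.size):.4f}")
    return "\n".join(lines) + "\n"


def write_solution_json(path, solution, report=None) -> None:
    with open(path, "w") as fh:
        json.dump(solution_to_dict(solution, report), fh, indent=2, sort_keys=True)
        fh.write("\n")
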