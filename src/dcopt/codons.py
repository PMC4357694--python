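"""Degenerate-codon algebra.

A degenerate codon (DC) is a codon whose three positions are each a non-empty
subset of the four nucleotides, written with the 15 IUPAC degenerate-nucleotide
letters (e.g. ``NNK``, ``NDT``).  A DC expands to the cartesian product of its
three sets; under a genetic code it produces a set of amino acids.  There are
(2^4 - 1)^3 = 3375 distinct DCs.

Amino acids are the 20 one-letter codes; the stop signal is carried as the
explicit 21st symbol ``*`` so that it can hold counts, penalties or a
forbidden flag like any other symbol.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

from .errors import CodonParseError

NUCLEOTIDES = "ACGT"

#: IUPAC degenerate-nucleotide letters -> the nucleotide subsets they denote.
IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_SET_TO_IUPAC = {frozenset(v): k for k, v in IUPAC_CODES.items()}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
#: The 21-symbol alphabet: 20 amino acids plus the stop symbol.
SYMBOLS = AMINO_ACIDS + STOP
SYMBOL_INDEX: Mapping[str, int] = {s: i for i, s in enumerate(SYMBOLS)}

# Standard genetic code in the classic TCAG layout: the i-th entry translates
# the codon whose bases are (TCAG[i>>4 & 3], TCAG[i>>2 & 3], TCAG[i & 3]).
_TCAG = "TCAG"
_STANDARD_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"


@dataclass(frozen=True)
class GeneticCode:
    """A total mapping from the 64 plain codons to the 21 symbols."""

    table: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must map all 64 codons, got {len(self.table)}")
        bad = {s for s in self.table.values() if s not in SYMBOL_INDEX}
        if bad:
            raise ValueError(f"genetic code maps to unknown symbols: {sorted(bad)}")

    @classmethod
    def standard(cls) -> "GeneticCode":
        table = {}
        for aa, (b1, b2, b3) in zip(_STANDARD_AAS, itertools.product(_TCAG, repeat=3)):
            table[b1 + b2 + b3] = aa
        return cls(table)

    def translate(self, codon: str) -> str:
        return self.table[codon.upper()]

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, s in self.table.items() if s == STOP)


STANDARD_CODE = GeneticCode.standard()


def _validate_mask(mask: Iterable[str]) -> frozenset[str]:
    m = frozenset(mask)
    if not m:
        raise ValueError("nucleotide mask must be non-empty")
    extra = m - set(NUCLEOTIDES)
    if extra:
        raise ValueError(f"nucleotide mask contains non-nucleotides: {sorted(extra)}")
    return m


@dataclass(frozen=True, order=False)
class DegenerateCodon:
    """An ordered triple of non-empty nucleotide subsets."""

    masks: tuple[frozenset[str], frozenset[str], frozenset[str]]

    def __post_init__(self) -> None:
        if len(self.masks) != 3:
            raise ValueError(f"a codon has exactly 3 positions, got {len(self.masks)}")
        object.__setattr__(self, "masks", tuple(_validate_mask(m) for m in self.masks))

    @classmethod
    def from_iupac(cls, text: str) -> "DegenerateCodon":
        return parse_iupac_codon(text)

    @property
    def iupac(self) -> str:
        """Canonical upper-case IUPAC string."""
        return "".join(_SET_TO_IUPAC[m] for m in self.masks)

    def expand(self) -> tuple[str, ...]:
        """All plain codons this DC defines, in lexicographic order."""
        return tuple(
            "".join(bases)
            for bases in itertools.product(*(sorted(m) for m in self.masks))
        )

    @property
    def degeneracy(self) -> int:
        """Number of plain DNA codons defined (product of mask sizes)."""
        n = 1
        for m in self.masks:
            n *= len(m)
        return n

    def amino_acids(self, code: GeneticCode = STANDARD_CODE) -> frozenset[str]:
        """The symbol set produced under ``code`` (may include ``*``)."""
        return frozenset(code.translate(c) for c in self.expand())

    def __lt__(self, other: "DegenerateCodon") -> bool:
        return self.iupac < other.iupac

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DegenerateCodon({self.iupac!r})"


def parse_iupac_codon(text: str) -> DegenerateCodon:
    """Parse a 3-letter IUPAC degenerate-nucleotide string, case-insensitively."""
    if not isinstance(text, str) or len(text) != 3:
        raise CodonParseError(f"expected a 3-letter IUPAC codon, got {text!r}")
    masks = []
    for ch in text:
        try:
            masks.append(frozenset(IUPAC_CODES[ch.upper()]))
        except KeyError:
            raise CodonParseError(
                f"{ch!r} in {text!r} is not an IUPAC degenerate-nucleotide letter"
            ) from None
    return DegenerateCodon(tuple(masks))


def format_iupac_codon(dc: DegenerateCodon) -> str:
    return dc.iupac


def degeneracy(dc: DegenerateCodon | str) -> int:
    return as_codon(dc).degeneracy


def expand(dc: DegenerateCodon | str) -> frozenset[str]:
    return frozenset(as_codon(dc).expand())


def amino_acid_set(dc: DegenerateCodon | str, code: GeneticCode = STANDARD_CODE) -> frozenset[str]:
    return as_codon(dc).amino_acids(code)


def as_codon(dc: DegenerateCodon | str) -> DegenerateCodon:
    """Coerce an IUPAC string (or pass through a codon) to a DegenerateCodon."""
    return dc if isinstance(dc, DegenerateCodon) else parse_iupac_codon(dc)


@lru_cache(maxsize=1)
def enumerate_all_codons() -> tuple[DegenerateCodon, ...]:
    """All 3375 degenerate codons, sorted by their IUPAC string."""
    masks = [frozenset(s) for s in IUPAC_CODES.values()]
    codons = [
        DegenerateCodon(triple) for triple in itertools.product(masks, repeat=3)
    ]
    return tuple(sorted(codons, key=lambda d: d.iupac))


# ---------------------------------------------------------------------------
# Fast integer views used by the position model and the DPs.  Symbol sets are
# 21-bit integers with bit i = SYMBOLS[i].

def symbols_to_bits(symbols: Iterable[str]) -> int:
    bits = 0
    for s in symbols:
        bits |= 1 << SYMBOL_INDEX[s]
    return bits


def bits_to_symbols(bits: int) -> frozenset[str]:
    return frozenset(s for s, i in SYMBOL_INDEX.items() if bits >> i & 1)


@lru_cache(maxsize=1)
def universe_tables() -> tuple[tuple[str, ...], Mapping[str, int], Mapping[str, int]]:
    """(iupac strings, degeneracy by string, symbol bitmask by string) for all 3375."""
    iupacs = []
    degs: dict[str, int] = {}
    bits: dict[str, int] = {}
    for dc in enumerate_all_codons():
        s = dc.iupac
        iupacs.append(s)
        degs[s] = dc.degeneracy
        bits[s] = symbols_to_bits(dc.amino_acids())
    return tuple(iupacs), degs, bits
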