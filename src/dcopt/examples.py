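"""Bundled library-design problems used in the documentation and tests.

Two real design problems ship with the package:

* ``surface_interface``: amino-acid counts from 200 design trajectories at
  nine surface positions of a protein-interface redesign, covered by two
  primer stretches; the experimental diversity budget is 3.2e8 (the size of
  the library an expert had built by hand for the same problem).
* ``lov2_jalpha``: counts from 1000 design trajectories at 12 positions near
  the J-alpha helix of the *Avena sativa* LOV2 domain, covered by five primer
  stretches, with a 1e9 diversity budget; each position's native (wild-type)
  amino acid is recorded and is usually required to stay encodable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .io import read_counts_table
from .library import StretchLayout
from .positions import PositionSpec


@dataclass(frozen=True)
class ExampleProblem:
    name: str
    positions: tuple[PositionSpec, ...]
    layout: StretchLayout
    diversity_limit: int
    native: dict[str, str]


def _load_counts(filename: str) -> list[PositionSpec]:
    with resources.as_file(resources.files("dcopt.data") / filename) as path:
        return read_counts_table(path)


def surface_interface() -> ExampleProblem:
    """Nine-position interface redesign; two stretches; no required symbols."""
    positions = _load_counts("surface_interface_counts.tsv")
    layout = StretchLayout(
        (("268", "269", "270", "271", "272", "276"), ("330", "331", "332"))
    )
    return ExampleProblem(
        name="surface_interface",
        positions=tuple(positions),
        layout=layout,
        diversity_limit=320_000_000,
        native={},
    )


#: Native amino acid at each lov2_jalpha position (bold in the source data).
LOV2_NATIVE = {
    "413": "K", "475": "E", "477": "T", "479": "Q", "493": "L", "495": "H",
    "514": "L", "520": "V", "528": "G", "529": "V", "531": "L", "532": "I",
}


def lov2_jalpha(require_native: bool = True) -> ExampleProblem:
    """Twelve-position LOV2 J-alpha redesign; five stretches.

    With ``require_native`` (the default) each position's wild-type amino
    acid must be covered by the chosen codon set (as a union condition),
    mirroring how the hand-built library guaranteed wild-type coverage.
    """
    positions = _load_counts("lov2_jalpha_counts.tsv")
    if require_native:
        positions = [
            PositionSpec(
                label=p.label,
                counts=p.counts,
                required=frozenset(LOV2_NATIVE[p.label]),
            )
            for p in positions
        ]
    layout = StretchLayout(
        (
            ("413",),
            ("475", "477", "479"),
            ("493", "495"),
            ("514", "520"),
            ("528", "529", "531", "532"),
        )
    )
    return ExampleProblem(
        name="lov2_jalpha",
        positions=tuple(positions),
        layout=layout,
        diversity_limit=1_000_000_000,
        native=dict(LOV2_NATIVE),
    )


#: The hand-designed codon sets for the two problems, kept for evaluation and
#: reporting examples.  The lov2 sets include the extra wild-type codon the
#: gene-fragment spiking technique contributes at each position, with the
#: leucine codon CTG at 520 that the designer intended.
SURFACE_INTERFACE_MANUAL = {
    "268": ("VDR",), "269": ("RBT",), "270": ("RYY",), "271": ("KCT",),
    "272": ("RBT",), "276": ("RVT",), "330": ("RVW",), "331": ("VNW",),
    "332": ("VVW",),
}

LOV2_JALPHA_MANUAL = {
    "413": ("GCC", "AAA"),
    "475": ("ARA", "GAG"),
    "477": ("KGG", "YWC", "ACC"),
    "479": ("RBA", "CAG"),
    "493": ("SNC", "TTG"),
    "495": ("KKC", "CAT"),
    "514": ("DDC", "WKG", "CTG"),
    "520": ("CTG", "GTG"),
    "528": ("RYG", "GGG"),
    "529": ("CDT", "RYG", "GTG"),
    "531": ("WGG", "CTG"),
    "532": ("GCC", "ATT"),
}
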