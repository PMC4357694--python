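"""Seeded synthetic counts tables for testing and benchmarking.

The generator emulates the shape of real design-trajectory tallies: each
position observes a small random subset of amino acids with multinomial
counts over a fixed number of trajectories.  Counts are what the optimizer
consumes; no sequence-level structure (e.g. residue-pair correlations) is
modelled.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .codons import AMINO_ACIDS
from .library import StretchLayout
from .positions import PositionSpec


def generate_fixture(
    n_positions: int,
    stretch_sizes: Sequence[int] | None = None,
    symbols_per_position: int = 4,
    total_per_position: int = 30,
    seed: int = 0,
) -> tuple[list[PositionSpec], StretchLayout]:
    """Draw a random counts table and stretch layout.

    Per position, ``symbols_per_position`` distinct amino acids are sampled
    and given multinomial counts summing to ``total_per_position`` (each
    sampled symbol is guaranteed at least one observation).  Deterministic
    under ``seed``.
    """
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    if not 1 <= symbols_per_position <= len(AMINO_ACIDS):
        raise ValueError(f"symbols_per_position must be in 1..{len(AMINO_ACIDS)}")
    if total_per_position < symbols_per_position:
        raise ValueError("total_per_position must cover one count per symbol")
    if stretch_sizes is None:
        stretch_sizes = [n_positions]
    if sum(stretch_sizes) != n_positions or any(s < 1 for s in stretch_sizes):
        raise ValueError(
            f"stretch_sizes {list(stretch_sizes)} must be positive and sum "
            f"to n_positions={n_positions}"
        )

    rng = np.random.default_rng(seed)
    labels = [str(i + 1) for i in range(n_positions)]
    specs = []
    for label in labels:
        symbols = rng.choice(list(AMINO_ACIDS), size=symbols_per_position, replace=False)
        extra = rng.multinomial(
            total_per_position - symbols_per_position,
            np.full(symbols_per_position, 1.0 / symbols_per_position),
        )
        counts = {
            str(sym): 1 + int(x) for sym, x in zip(symbols, extra)
        }
        specs.append(PositionSpec(label=label, counts=counts))

    stretches = []
    at = 0
    for size in stretch_sizes:
        stretches.append(tuple(labels[at : at + size]))
        at += size
    return specs, StretchLayout(tuple(stretches))
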