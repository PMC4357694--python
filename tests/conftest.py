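import numpy as np
import pytest

from dcopt.codons import universe_tables
from dcopt.examples import lov2_jalpha, surface_interface
from dcopt.library import LibrarySolution, PositionAssignment
from dcopt.positions import build_position_table, codon_set_error, codon_set_size


@pytest.fixture(scope="session")
def surface_problem():
    return surface_interface()


@pytest.fixture(scope="session")
def lov2_problem():
    return lov2_jalpha()


@pytest.fixture(scope="session")
def surface_tables_lp3(surface_problem):
    """Position tables for the interface problem at up to three codons.

    Entries at smaller codon counts are the same tables the lower-limit runs
    use, so one build serves every solver configuration.
    """
    return [build_position_table(p, 3) for p in surface_problem.positions]


@pytest.fixture(scope="session")
def lov2_tables_lp3(lov2_problem):
    return [build_position_table(p, 3) for p in lov2_problem.positions]


def sample_candidates(seed: int, n: int) -> list[str]:
    """A deterministic random subset of the 3375-codon universe."""
    iupacs, _, _ = universe_tables()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(iupacs), size=n, replace=False)
    return sorted(iupacs[i] for i in idx)


def manual_solution(positions, codon_sets) -> LibrarySolution:
    """Assemble a LibrarySolution from hand-specified codon sets."""
    assignments = []
    size = 1
    error = 0
    for p in positions:
        codons = tuple(codon_sets[p.label])
        e = codon_set_error(p, codons)
        s = codon_set_size(codons)
        assignments.append(PositionAssignment(p.label, codons, e, s))
        size *= s
        error += e
    return LibrarySolution(tuple(assignments), error, size)
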