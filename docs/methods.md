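# Methods

## Model

A design problem is a list of positions, each with integer amino-acid counts
`C_i(a)` over the 21-symbol alphabet (20 amino acids plus `*` for stop),
optional integer penalties, and required/forbidden symbols; a partition of
the positions into contiguous primer stretches; a diversity limit `L`; and
primer budgets `L_p` (codons per position), `L_s` (primers per stretch) and
`L_T` (primers total), with `1 ≤ L_p ≤ L_s ≤ L_T` and `L_T` at least the
number of stretches. The objective is linearly additive over positions and
deliberately ignores residue-pair information: optimizing pairwise coverage
is NP-complete, while the per-position objective admits an exact
polynomial-time dynamic program.

Choices baked into the error model:

* **Codon-set error is a union condition.** A set's error is computed on the
  union of its members' amino-acid sets; penalties are charged once per
  penalized symbol present in the union, not per codon.
* **Required symbols are a union condition too** for multi-codon sets (no
  single member must cover them); for the single-codon program the union is
  the codon itself, which reduces to a per-codon filter.
* **Set size is the sum of member degeneracies**, even if expansions
  overlap: physically, each codon is a separate primer mix. Overlapping sets
  are dominated and never optimal, so this convention is also safe.
* **Stop is an ordinary symbol.** It can carry counts, a penalty or a
  forbidden flag; by default it is unpenalized and allowed, matching how the
  bundled problems were posed (one published optimum for the LOV2 problem
  contains a stop-producing codon, so reproduction requires this default).
* All counts/penalties are integers; real-valued weights are out of scope
  because the DP indexes tables by error.

## Per-position tables

`build_position_table` computes `s_i[j', e']`: the minimal combined DNA size
over sets of exactly `j'` distinct admissible codons with union error `e'`,
plus one witness set. Admissibility excludes codons producing a forbidden
symbol. The search space is reduced by **coverage classes**: only the
subset of symbols that are counted, penalized or required affects error and
feasibility, so codons are grouped by that coverage signature. Within a
class, only the smallest codons matter; we keep the `L_p` smallest per class
(not just one) so that minima over sets of *exactly* `j'` distinct codons
are preserved even when an optimal set draws several members from one class.
A 0/1-knapsack pass over the representatives (layers = set cardinality,
states = coverage signatures) then yields all `(j', e')` minima with
distinctness guaranteed by construction. Building the tables with and
without the reduction gives identical results (tested), the reduction merely
makes the full problems fast (hundreds of representatives instead of 3375
codons).

## Dynamic programs

Both solvers invert the constrained problem into "smallest library at each
error level", then take the first level whose minimal size fits `L`.

* **Single-codon DP:** `S[i, e] = min over e' of S[i-1, e-e'] * s_i[1, e']`,
  with a traceback table of the per-position error choices. The lower bound
  of the `e'` minimization includes 0 (zero-error contributions are legal
  and occur in the bundled optima).
* **Multi-codon DP:** the state is (position i, total primers j, primers k
  used by i's stretch, error e). At the first position of a stretch the
  previous stretch's primer count is minimized out and `k` starts at the
  number of codons chosen; within a stretch, choosing `j'` codons multiplies
  `k` by `j'` and adds `(j'-1)·k_prev` to the total. Only divisor
  transitions (`k/j'` integral) exist. `k ≤ L_s` is enforced throughout the
  recursion, not just at readout (equivalent optima, simpler invariants).
  Tables are stored sparsely (dict keyed by error, then by (j, k)): most
  states are unreachable.

Modes: **lazy** (default) iterates total error outermost and stops at the
first feasible level, touching only errors `0..optimum` — the bundled
problems finish in seconds this way; **full** populates every error level up
to `Σ m_i` and yields the complete Pareto front (error, minimal size), so a
user can see what relaxing the limit would buy without re-running.

Library sizes are exact Python integers throughout (the bundled problems
exceed 10⁸, beyond exact float range for products); serialized sizes are
decimal strings.

Tie-breaking is deterministic everywhere: smallest error contribution first,
then fewest codons, then the lexicographically smallest IUPAC witness tuple.
Published codon *identities* are therefore not guaranteed to be reproduced
when ties exist — only the (error, size) optima are unique — and the test
suite asserts the numeric optima, not the witnesses.

## Reports

Per position: the codon set, its amino-acid union, DNA count (#NA, expanded
codons with multiplicity), distinct amino-acid count (#AA, stop excluded)
and the fraction of expanded codons translating to a *desired* symbol (one
with a positive count). Totals are products across positions; the fraction
of library members containing only desired amino acids and the AA:DNA ratio
are kept as exact rationals and rounded only at render time (nearest integer
per position, one decimal for totals). Stop codons and unobserved amino
acids count as undesired.

## Bundled problems and known data quirks

Two real problems ship as counts tables: a 9-position interface redesign
(200 trajectories, two stretches, limit 3.2 × 10⁸) and a 12-position LOV2
J-alpha redesign (1000 trajectories, five stretches, limit 10⁹, with each
position's native amino acid required). Known quirks of the original
hand-evaluated solution tables, documented rather than reproduced:

* The hand-built interface library's printed error at position 268 (29) is
  inconsistent with the error function applied to the printed counts and
  VDR's amino-acid set, which gives 31 (total 124, not 122). The package
  follows the error function.
* The hand-built LOV2 library's printed #AA at position 493 (9) does not
  match its printed 8-symbol amino-acid set; the report recomputes.
* The LOV2 manual library is evaluated with the wild-type codon included at
  each position (the bench technique spikes wild-type gene fragments in) and
  with the leucine codon CTG at position 520 that its designer intended to
  order.

## Synthetic fixtures

`generate_fixture` draws, per position, a small set of distinct amino acids
and multinomial counts over a fixed number of observations (each drawn
symbol gets at least one count), plus a stretch partition; everything is
deterministic under a seed. It emulates the *shape* of design-trajectory
tallies — sparse per-position amino-acid usage with skewed counts — but not
residue-pair correlation or any structural signal, so oracle-equivalence
results on fixtures certify the optimizer's correctness, not the biological
quality of libraries built from real data. Test instances are kept small
(2–3 positions, ~10–15 candidate codons, counts of 12–30) so that the
brute-force oracle — exhaustive enumeration over codon-set assignments,
shared candidate lists with the DP under test — stays exact and fast; the
sweep covers 220+ seeded instances plus limit-monotonicity and
self-consistency checks.

## Limitations

* Stretch boundaries are inputs; jointly optimizing them with codons (which
  would need G/C content and annealing temperatures) is out of scope, as is
  primer sequence emission.
* No spiked (non-uniform nucleotide ratio) codons.
* No sequence-level scores: objectives that count fully covered input
  sequences require the input sequence sets themselves, not counts.
* The full-table mode is quadratic in the total error mass and is intended
  for small problems or truncated error ranges; the lazy mode is the
  production path.
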