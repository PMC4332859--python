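# Methods

## Problem

A multiplexed sequencing library labels each sample's fragments with a
short oligonucleotide *tag* (barcode). Synthesis, amplification, and
sequencing introduce substitutions *and* insertions/deletions, so tags are
designed as an **edit-metric code**: a set S of length-n words over
{A, C, G, T} whose pairwise Levenshtein distances are all at least d. A
distance-d code detects d−1 arbitrary single-base errors and corrects
⌊(d−1)/2⌋, including the indels that Hamming-metric barcodes cannot
handle. The design goal is a *constructive lower bound*: the largest set
achievable for a given (n, d) under biological side constraints.

## Constraint profile

`ConstraintProfile` bundles the rules a set must satisfy:

- **Minimum pairwise edit distance d** (unit-cost Levenshtein, no
  transposition operation). The tag-to-set distance TTE(u) =
  min_{v ∈ S, v ≠ u} E(u, v) must be ≥ d for every tag.
- **GC content**, two modes. *Range* mode keeps each tag's GC percentage
  within an inclusive window (default 40–60%, the conventional band).
  *Fixed* mode requires exactly ⌊n/2⌋ G/C bases per tag (configurable),
  pinning every tag to one GC composition; the two modes coincide exactly
  at n = 4, 6, 8, where the only integer count inside 40–60% is n/2.
- **Continuity**: the longest homopolymer run within any tag is capped
  (default 2); longer runs destabilize the duplex and inflate sequencing
  error.
- **Complementarity**. *Self* mode excludes tags equal to their own
  reverse complement (they can hybridize with copies of themselves).
  *Cross* mode excludes any tag equal to the reverse complement of any
  tag in the set — the self rule is its i = j special case — preventing
  tag–tag hybridization across samples. "Complement" always means
  reverse complement with both strands written 5′→3′ (GTCAA ↔ TTGAC;
  AATT is its own complement).

## The greedy-closure genetic algorithm

The designer maintains two collections: an evolving population of
candidate words and a monotonically growing **result set**. An
individual's fitness is its TTE against the result set; every individual
reaching fitness ≥ d (and passing the single-tag rules) is appended to
the set as the generations proceed, with the TTE re-checked against the
set *as already enlarged within the same generation* so that two near
neighbors discovered together cannot both enter. This greedy closure is
what turns a fitness-maximizing GA into a set constructor.

Operating point (defaults of `GAConfig`): population 500, 200
generations, crossover rate 0.45, binary tournaments repeated for 10% of
the population, dynamic per-base mutation — 0.01 for individuals above
the population-mean fitness, 0.03 at the mean (tolerance 1e-9), 0.3
below it. The initial population is placed *equidistantly* over the
integer encoding of the word space (indices ⌊i·4ⁿ/k⌋), giving global
coverage that a random initialization lacks. When no tag has been
appended for 20 consecutive generations the population is re-randomized,
at most once per run, to escape premature convergence.

Design choices where the procedure was genuinely open:

- **Reproduction is steady-state.** Each generation the tournament
  winners produce one three-point-crossover child each; children replace
  the 10% lowest-fitness individuals and the whole population then
  mutates at its dynamic rates, children inheriting the rate of the
  winner contributing their first segment. We first implemented full
  generational replacement bred from the small winner pool; it collapses
  diversity and measurably weakens the constructive bounds at high d
  (best-of-50 runs failed to reach set sizes that the steady-state
  scheme reaches with the same budget). Both schemes are consistent with
  the stated tournament parameters; the steady-state one is kept.
- **Banked duplicates are lethal.** An individual identical to a tag
  already in the result set is scored 0 rather than its
  distance-to-the-rest: every word within distance d of a banked tag is
  permanently excluded, so rewarding that neighborhood anchors the
  search on ground that cannot yield new tags. This single change
  roughly quintupled the hit rate of the hardest design cells.
- **Seeding.** The first result-set element is the first individual, in
  scan order from a seeded random offset, that passes the single-tag
  rules — without this filter the closure invariant (every emitted set
  passes its own profile) would break on the very first tag.
- **Mutation always changes the base** (uniform over the other three);
  infinity-sentinel fitness (empty result set) counts as above-mean and
  is excluded from the mean itself.

All randomness flows from a single integer seed through one
`numpy.random.Generator`; identical (n, profile, config) reproduce
byte-identical sets and logs.

### What a greedy closure cannot do

Appending is irrevocable, so the final size depends heavily on which
tags happen to be banked first. On the exhaustively solvable instance
n = 4, d = 3 (range GC, continuity ≤ 2, self-complementarity excluded)
the exact maximum — computed as a maximum clique of the compatibility
graph over the 88 admissible words and independently re-verified — is
12, yet random-order greedy closures reach 12 in only ≈0.25% of
orderings (and never 11; the instance has a parity structure). The GA
typically banks 8–10. Any greedy-closure design, ours or otherwise,
should be read as a *lower-bound constructor*, not an exact packer.
Relatedly, plain greedy lexicodes are strong exactly where sets are
large (low d): our lexicographic baseline reaches 207 tags at
n = 7, d = 3, where the GA's best-of-few-runs is ≈170. The GA's value
is concentrated at high d, where the lexicode's fixed scan order leaves
sizeable gaps (e.g. 5 vs 4 at n = 7, d = 6, or 5 vs 4 at n = 10, d = 8
under the fixed-GC profile).

## Baselines and oracles

- `greedy_lexicode`: scans the filtered word pool in lexicographic order
  (A < C < G < T, any permutation injectable) and keeps every compatible
  word. Deterministic; validity is ordering-independent.
- `brute_force_optimum`: exact maximum-cardinality compatible subset via
  `networkx` maximum-clique branch-and-bound on the filtered pool;
  restricted to n ≤ 5 where the pool is small. Used as the upper oracle
  in the sandwich greedy ≤ GA ≤ optimum.

## Melting temperatures

Per-tag Tm uses the two-state nearest-neighbor model: ΔH and ΔS are
summed over consecutive dinucleotide stacks (the unified DNA/DNA
parameter table, shipped as `data/nn_unified.json`) plus
duplex-initiation terms for the two terminal pairs, then

Tm(°C) = 1000·ΔH / (ΔS + R·ln(C_T/4)) − 273.15,

with R = 1.987 cal/(mol·K), C_T the total strand concentration
(default 0.25 µM, the two-state non-self-complementary C_T/4 form), and
the entropy salt correction 0.368·(N−1)·ln[Na⁺] (default 50 mM Na⁺).
The set-level quality metric is the **Tm gap**, |max Tm − min Tm| over
the set: the smaller the gap, the more uniformly the tags hybridize at
one annealing temperature. Fixing the G/C count (fixed GC mode) pins
the largest Tm determinant and demonstrably tightens the gap relative
to range-mode sets — the package asserts this as a statistical trend
over 50 paired random sets, not per-set.

Published Tm-gap tables for specific historical tag sets are *not*
reproduction targets: they depend on reaction conditions and parameter
choices that were never printed, and on the exact member sequences of
those sets. Valid tag sets never contain self-complementary tags, so
the C_T/4 form is used uniformly; scoring a palindromic sequence anyway
emits a warning. Mismatch and dangling-end corrections and divalent
cations are out of scope.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` exercise the full operating
point (population 500, 200 generations) on the high-distance cells
n = 10, d = 8 (fixed GC, self) and n = 10, d = 9 (fixed GC, cross) with
50 seeded runs each — the cells where a desk-scale machine can match
the published bounds — and scaled-down populations (60–150) for closure
and determinism properties, which are size-independent. Low-d cells
with thousands of tags require orders of magnitude more compute and are
supported but not routinely executed.

## The fixture generator

`generate_fixture_set` rejection-samples random tags under the
single-tag rules (optionally the pairwise rule, greedily), seeded and
reproducible, and can plant a deliberate cross-complement violation. It
emulates *composition*, not the distance geometry of designed sets:
random sets say nothing about achievable code sizes, and tests built on
them only exercise validators and the Tm machinery, not design quality.

## Known limitations

- Set sizes for low d are below the best published constructions at
  n ≥ 6; the greedy closure is the binding factor (see above).
- Exact optima are only available for n ≤ 5; for larger n the only
  upper bounds are trivial.
- The thermodynamic model is two-state and monovalent-salt only.
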