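"""Greedy-closure genetic algorithm for growing DNA tag sets.

The designer evolves a population of candidate tags over the 4**n word
space while maintaining a separate, monotonically growing *result set*.
An individual's fitness is its tag-tag edit distance (TTE) to the result
set -- the distance to its nearest neighbor among the tags already kept --
and every individual whose fitness reaches the distance threshold d (and
which passes the composition rules) is appended to the set as the
generations proceed.  The search is thus a maximization of TTE, with the
result set acting as a greedy closure over everything the population
discovers.

Departures from a textbook GA, all aimed at global coverage of the word
space: the initial population is placed *equidistantly* across [0, 4**n)
rather than sampled randomly; the per-base mutation probability is set
dynamically from each individual's fitness relative to the population mean
(0.01 above the mean, 0.03 at it, 0.3 below it); and the population may be
randomly re-initialized once, when growth stalls, to escape premature
convergence.

Reproduction is steady-state: each generation, binary tournaments repeated
for 10% of the population pick winners, one three-point-crossover child
per winner replaces one of the 10% lowest-fitness individuals, and the
whole population then mutates at the dynamic rates (children at the rate
of the winner contributing their first segment).  Individuals identical
to a tag already banked in the result set are scored lethal (fitness 0):
everything within distance d of a banked tag is excluded anyway, so
rewarding its neighborhood would anchor the search on ground that cannot
yield new tags.

Internals operate on (population_size, n) uint8 code matrices; sequences
cross the string boundary only when appended to the result set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constraints import (
    INFINITY,
    ConstraintProfile,
    TagSet,
    batch_edit_distance,
    tte,
)
from .sequences import decode, encode

_RATE_TOL = 1e-9


@dataclass
class Individual:
    """A candidate tag plus its TTE-based fitness (scalar API convenience)."""

    sequence: str
    fitness: float = INFINITY


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the modified GA.

    Defaults are the designer's operating point: population 500, crossover
    rate 0.45, dynamic mutation starting at 0.01, 200 generations, binary
    tournaments repeated for 10% of the population, one stall-triggered
    re-initialization.
    """

    population_size: int = 500
    crossover_rate: float = 0.45
    mutation_rate_base: float = 0.01  # fitness above the population mean
    mutation_rate_equal: float = 0.03  # fitness at the mean
    mutation_rate_low: float = 0.3  # fitness below the mean
    generations: int = 200
    tournament_size: int = 2
    tournament_fraction: float = 0.10
    reinit_policy: str = "stall"  # {"stall", "off"}
    stall_generations: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "mutation_rate_base", "mutation_rate_equal",
                     "mutation_rate_low", "tournament_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.reinit_policy not in ("stall", "off"):
            raise ValueError(f"unknown reinit_policy {self.reinit_policy!r}")


# ---------------------------------------------------------------------------
# building blocks (each also usable on its own)


def init_population_even(k: int, n: int) -> list[str]:
    """The k length-n words spaced equidistantly across the 4**n space.

    Individual i is the word with base-4 index floor(i * 4**n / k); the
    gaps between consecutive indices differ by at most one.  Deterministic.
    """
    space = 4**n
    if k < 1:
        raise ValueError("population size must be >= 1")
    if k > space:
        raise ValueError(f"population of {k} exceeds the 4^{n} = {space} word space")
    return [decode(_index_to_codes(i * space // k, n)) for i in range(k)]


def _index_to_codes(index: int, n: int) -> np.ndarray:
    out = np.empty(n, dtype=np.uint8)
    for pos in range(n - 1, -1, -1):
        out[pos] = index & 3
        index >>= 2
    return out


def fitness(sequence: str, members: Sequence[str], profile: ConstraintProfile) -> float:
    """Fitness of one candidate against the current result set.

    Zero (lethal) if the candidate breaks any single-tag rule, violates the
    cross-complement rule against the set, or duplicates a banked tag (its
    whole d-neighborhood is already excluded, so it cannot lead anywhere
    new); otherwise its TTE, with the infinity sentinel against an empty
    set.
    """
    from .constraints import _single_tag_reasons, reverse_complement

    from .sequences import canonicalize

    sequence = canonicalize(sequence)
    if _single_tag_reasons(sequence, profile):
        return 0.0
    if any(canonicalize(v) == sequence for v in members):
        return 0.0
    if profile.complementarity == "cross":
        rc = reverse_complement(sequence)
        if any(canonicalize(v) == rc for v in members):
            return 0.0
    return tte(sequence, members)


def dynamic_mutation_rate(fit: float, population_mean: float, config: GAConfig | None = None) -> float:
    """Per-base mutation probability from fitness relative to the mean.

    Above the mean -> low rate (exploit a good individual); at the mean ->
    slightly higher; below -> aggressive (0.3) to relocate poor individuals.
    Infinity-sentinel fitness counts as above the mean.
    """
    config = config or GAConfig()
    if math.isinf(fit):
        return config.mutation_rate_base
    if fit > population_mean + _RATE_TOL:
        return config.mutation_rate_base
    if abs(fit - population_mean) <= _RATE_TOL:
        return config.mutation_rate_equal
    return config.mutation_rate_low


def tournament_select(fits: np.ndarray, config: GAConfig, rng: np.random.Generator) -> np.ndarray:
    """Indices of the winners of ceil(fraction * population) tournaments.

    Each tournament draws ``tournament_size`` contestants uniformly with
    replacement; the highest fitness wins, ties broken uniformly at random.
    """
    k = len(fits)
    if k == 0:
        raise ValueError("empty population")
    t = min(max(math.ceil(config.tournament_fraction * k), 1), k)
    draws = rng.integers(0, k, size=(t, config.tournament_size))
    winners = np.empty(t, dtype=np.int64)
    for row in range(t):
        contestants = draws[row]
        vals = fits[contestants]
        best = contestants[vals == vals.max()]
        winners[row] = best[0] if len(best) == 1 else rng.choice(best)
    return winners


def three_point_crossover(
    parent1: str, parent2: str, config: GAConfig, rng: np.random.Generator
) -> tuple[str, str]:
    """Exchange alternating segments between two equal-length parents.

    With probability ``crossover_rate``, three distinct cut positions are
    drawn from the n-1 internal boundaries and the segments between them
    are swapped alternately; otherwise the children are copies.  For n < 4
    there are fewer than three internal boundaries, so a single-point
    crossover is used instead.
    """
    p1, p2 = encode(parent1), encode(parent2)
    if len(p1) != len(p2):
        raise ValueError("parents must have equal length")
    n = len(p1)
    if rng.random() >= config.crossover_rate:
        return parent1, parent2
    n_cuts = 3 if n >= 4 else 1
    cuts = rng.choice(np.arange(1, n), size=n_cuts, replace=False)
    swap = _swap_mask(cuts[None, :], n)[0]
    c1 = np.where(swap, p2, p1)
    c2 = np.where(swap, p1, p2)
    return decode(c1), decode(c2)


def _swap_mask(cuts: np.ndarray, n: int) -> np.ndarray:
    """(npairs, n) bool: positions lying in odd-numbered inter-cut segments."""
    positions = np.arange(n)
    crossed = positions[None, None, :] >= cuts[:, :, None]
    return (crossed.sum(axis=1) % 2).astype(bool)


@dataclass
class GAState:
    """Mutable bookkeeping carried across generations."""

    stall_counter: int = 0
    reinit_used: bool = False


def maybe_reinitialize(
    pop: np.ndarray, state: GAState, config: GAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Replace the population with uniform random individuals, at most once.

    Fires when no tag has been appended for ``stall_generations``
    consecutive generations; the result set is untouched.  A second stall
    leaves the population alone -- repeated restarts would stop the search
    from ever converging.
    """
    if (
        config.reinit_policy == "stall"
        and not state.reinit_used
        and state.stall_counter >= config.stall_generations
    ):
        state.reinit_used = True
        state.stall_counter = 0
        return rng.integers(0, 4, size=pop.shape, dtype=np.uint8)
    return pop


# ---------------------------------------------------------------------------
# vectorized per-population rule checks


def _single_tag_mask(pop: np.ndarray, profile: ConstraintProfile) -> np.ndarray:
    k, n = pop.shape
    ok = np.ones(k, dtype=bool)
    gc = ((pop == 1) | (pop == 2)).sum(axis=1)
    if profile.gc_mode == "fixed":
        ok &= gc == profile.fixed_count_for(n)
    elif profile.gc_mode == "range":
        pct = gc * (100.0 / n)
        ok &= (pct >= profile.gc_min) & (pct <= profile.gc_max)
    run = np.ones(k, dtype=np.int32)
    best = np.ones(k, dtype=np.int32)
    for j in range(1, n):
        same = pop[:, j] == pop[:, j - 1]
        run = np.where(same, run + 1, 1)
        np.maximum(best, run, out=best)
    ok &= best <= profile.continuity_max
    if profile.excludes_self_complementary:
        rc = (3 - pop)[:, ::-1]
        ok &= ~(pop == rc).all(axis=1)
    return ok


def _masked_distance(pop: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Distances to ``target`` with rows equal to it mapped to infinity.

    The TTE minimum runs over *distinct* set members, so an individual
    identical to a tag already in the set does not see its own zero.
    """
    dists = batch_edit_distance(pop, target).astype(float)
    eq = (pop == target).all(axis=1)
    dists[eq] = INFINITY
    return dists


def _population_tte(pop: np.ndarray, set_codes: list[np.ndarray]) -> np.ndarray:
    """TTE of every row against the result set, deduplicating identical rows."""
    k = pop.shape[0]
    if not set_codes:
        return np.full(k, INFINITY)
    uniq, inverse = np.unique(pop, axis=0, return_inverse=True)
    best = np.full(uniq.shape[0], INFINITY)
    for target in set_codes:
        np.minimum(best, _masked_distance(uniq, target), out=best)
    return best[inverse]


# ---------------------------------------------------------------------------
# the full designer


@dataclass
class GenerationRecord:
    generation: int
    set_size: int
    mean_fitness: float
    max_fitness: float

    def as_tsv_row(self) -> str:
        mx = "inf" if math.isinf(self.max_fitness) else f"{self.max_fitness:.6g}"
        return f"{self.generation}\t{self.set_size}\t{self.mean_fitness:.6f}\t{mx}"


LOG_HEADER = "generation\tset_size\tmean_fitness\tmax_fitness"


def log_to_tsv(log: Sequence[GenerationRecord]) -> str:
    return "\n".join([LOG_HEADER, *(rec.as_tsv_row() for rec in log)]) + "\n"


def evolve(
    n: int, profile: ConstraintProfile, config: GAConfig | None = None
) -> tuple[TagSet, list[GenerationRecord]]:
    """Run the greedy-closure GA and return the designed set plus its log.

    The result set always satisfies its own profile: every append re-checks
    the candidate's TTE against the set *as already enlarged this
    generation*, so two near neighbors discovered together cannot both
    enter.  Fully deterministic for a fixed (n, profile, config).
    """
    config = config or GAConfig()
    profile.check_feasible(n)
    rng = np.random.default_rng(config.seed)
    k = min(config.population_size, 4**n)

    pop = np.stack([encode(s) for s in init_population_even(k, n)])
    state = GAState()
    tags: list[str] = []
    set_codes: list[np.ndarray] = []

    def _append(row: np.ndarray) -> None:
        tags.append(decode(row))
        set_codes.append(row.copy())

    # seed the result set: first individual, scanning from a random offset,
    # that satisfies the single-tag rules
    single_ok = _single_tag_mask(pop, profile)
    start = int(rng.integers(0, k))
    for j in range(k):
        i = (start + j) % k
        if single_ok[i]:
            _append(pop[i])
            break

    log: list[GenerationRecord] = []
    for gen in range(1, config.generations + 1):
        single_ok = _single_tag_mask(pop, profile)
        tte_arr = _population_tte(pop, set_codes)
        dup, crossc = _set_conflicts(pop, set_codes, profile)

        appended = 0
        candidates = np.flatnonzero(single_ok)
        for i in candidates:
            if dup[i] or crossc[i] or tte_arr[i] < profile.d:
                continue
            row = pop[i]
            _append(row)
            appended += 1
            np.minimum(tte_arr, _masked_distance(pop, row), out=tte_arr)
            eq = (pop == row).all(axis=1)
            dup |= eq
            if profile.complementarity == "cross":
                rc = (3 - row)[::-1]
                crossc |= (pop == rc).all(axis=1)

        fits = np.where(single_ok & ~crossc & ~dup, tte_arr, 0.0)
        finite = fits[np.isfinite(fits)]
        mean_fit = float(finite.mean()) if finite.size else 0.0
        log.append(
            GenerationRecord(gen, len(tags), mean_fit, float(fits.max()) if k else 0.0)
        )

        state.stall_counter = 0 if appended else state.stall_counter + 1

        pop = _next_generation(pop, fits, mean_fit, config, rng)
        pop = maybe_reinitialize(pop, state, config, rng)

    result = TagSet(tags=tags, profile=profile)
    return result, log


def _set_conflicts(
    pop: np.ndarray, set_codes: list[np.ndarray], profile: ConstraintProfile
) -> tuple[np.ndarray, np.ndarray]:
    """(duplicate-of-set, cross-complement-of-set) masks for every row."""
    k = pop.shape[0]
    dup = np.zeros(k, dtype=bool)
    crossc = np.zeros(k, dtype=bool)
    if set_codes:
        set_mat = np.stack(set_codes)
        dup = (pop[:, None, :] == set_mat[None, :, :]).all(axis=2).any(axis=1)
        if profile.complementarity == "cross":
            rc_mat = (3 - set_mat)[:, ::-1]
            crossc = (pop[:, None, :] == rc_mat[None, :, :]).all(axis=2).any(axis=1)
    return dup, crossc


def _next_generation(
    pop: np.ndarray,
    fits: np.ndarray,
    mean_fit: float,
    config: GAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Steady-state reproduction: winners breed, offspring replace the worst,
    then the whole population mutates at its dynamic rates."""
    k, n = pop.shape

    winners = tournament_select(fits, config, rng)
    t = len(winners)
    pa = pop[winners]
    pb = pop[winners[rng.permutation(t)]]

    do_cross = rng.random(t) < config.crossover_rate
    n_cuts = min(3, max(n - 1, 1))
    # distinct uniform cut positions per crossing pair via random-key sort
    keys = rng.random((t, max(n - 1, 1)))
    cuts = np.argsort(keys, axis=1)[:, :n_cuts] + 1
    swap = _swap_mask(cuts, n) & do_cross[:, None]
    children = np.where(swap, pb, pa)

    rates = np.where(
        np.isinf(fits) | (fits > mean_fit + _RATE_TOL),
        config.mutation_rate_base,
        np.where(
            np.abs(fits - mean_fit) <= _RATE_TOL,
            config.mutation_rate_equal,
            config.mutation_rate_low,
        ),
    )
    worst = np.argsort(fits, kind="stable")[:t]
    pop = pop.copy()
    pop[worst] = children
    rates[worst] = rates[winners]  # children mutate at their first parent's rate

    mut = rng.random((k, n)) < rates[:, None]
    offsets = rng.integers(1, 4, size=(k, n), dtype=np.uint8)
    return np.where(mut, (pop + offsets) % 4, pop).astype(np.uint8)


@dataclass
class ExperimentResult:
    """Best set over repeated seeded runs, plus the per-run size distribution."""

    best: TagSet
    sizes: list[int]
    seeds: list[int]
    logs: list[list[GenerationRecord]] = field(default_factory=list, repr=False)

    @property
    def max_size(self) -> int:
        return max(self.sizes)


def run_experiments(
    n: int,
    profile: ConstraintProfile,
    config: GAConfig | None = None,
    runs: int = 1,
    keep_logs: bool = False,
) -> ExperimentResult:
    """Repeat :func:`evolve` with seeds ``seed .. seed+runs-1``; keep the best.

    Tag-set construction is stochastic, so repeated runs tighten the
    constructive lower bound: the reported maximum is non-decreasing in
    ``runs``.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    config = config or GAConfig()
    best: TagSet | None = None
    sizes: list[int] = []
    seeds: list[int] = []
    logs: list[list[GenerationRecord]] = []
    for r in range(runs):
        cfg = replace(config, seed=config.seed + r)
        tag_set, log = evolve(n, profile, cfg)
        sizes.append(len(tag_set))
        seeds.append(cfg.seed)
        if keep_logs:
            logs.append(log)
        if best is None or len(tag_set) > len(best):
            best = tag_set
    assert best is not None
    return ExperimentResult(best=best, sizes=sizes, seeds=seeds, logs=logs)
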