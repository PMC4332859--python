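"""Constraint mathematics for DNA tag sets.

A tag set S is a collection of same-length words over {A, C, G, T} that are
mutually far apart in Levenshtein (edit) distance and individually satisfy
composition rules: GC content (a 40-60% window or an exact G/C count),
a homopolymer-run cap ("continuity"), and optional complementarity
exclusions.  The minimum pairwise edit distance d of the set determines how
many synthesis/sequencing errors can be detected or corrected when the tags
are used as multiplexing barcodes.

This module holds the metric itself (:func:`edit_distance`), the tag-to-set
distance :func:`tte`, the :class:`ConstraintProfile` bundle, and the
validators used both by the designers and by the CLI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .sequences import (
    canonicalize,
    encode,
    gc_content,
    gc_count,
    is_self_complementary,
    longest_run,
    reverse_complement,
)

#: Sentinel returned by :func:`tte` when the reference set imposes no
#: constraint (empty, or containing only the query itself): any minimum
#: distance requirement is vacuously satisfied.
INFINITY = math.inf


class EmptySetError(ValueError):
    """Raised by set-level statistics that are undefined on an empty set."""


class LengthMismatchError(ValueError):
    """Raised when tags of different lengths are mixed in one set."""


def edit_distance(u: str, v: str) -> int:
    """Unit-cost Levenshtein distance between two DNA words.

    The minimum number of single-base insertions, deletions, or
    substitutions transforming ``u`` into ``v`` (no transposition
    operation).  Computed by the classic two-row dynamic program.
    """
    u = canonicalize(u)
    v = canonicalize(v)
    if len(u) < len(v):
        u, v = v, u
    prev = list(range(len(v) + 1))
    for i, cu in enumerate(u, start=1):
        curr = [i] + [0] * len(v)
        for j, cv in enumerate(v, start=1):
            curr[j] = min(prev[j] + 1, curr[j - 1] + 1, prev[j - 1] + (cu != cv))
        prev = curr
    return prev[-1]


def batch_edit_distance(pop: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Levenshtein distance from every row of ``pop`` to ``target``.

    ``pop`` is a (k, n) uint8 code matrix, ``target`` a length-m code
    vector; returns a length-k int array.  Same unit-cost dynamic program
    as :func:`edit_distance`, vectorized across the population -- this is
    the GA engine's hot path.
    """
    pop = np.asarray(pop)
    k, n = pop.shape
    m = len(target)
    prev = np.broadcast_to(np.arange(n + 1), (k, n + 1)).copy()
    curr = np.empty_like(prev)
    for i in range(1, m + 1):
        curr[:, 0] = i
        for j in range(1, n + 1):
            cost = (pop[:, j - 1] != target[i - 1]).astype(prev.dtype)
            np.minimum(prev[:, j] + 1, curr[:, j - 1] + 1, out=curr[:, j])
            np.minimum(curr[:, j], prev[:, j - 1] + cost, out=curr[:, j])
        prev, curr = curr, prev
    return prev[:, n].copy()


def tte(u: str, members: Iterable[str]) -> float:
    """Tag-tag edit distance: min edit distance from ``u`` to the set.

    Members equal to ``u`` itself are excluded from the minimum.  Returns
    :data:`INFINITY` when no distinct member exists, so the first tag of a
    growing set is accepted for any distance threshold.
    """
    u = canonicalize(u)
    best = INFINITY
    for v in members:
        v = canonicalize(v)
        if v == u:
            continue
        dist = edit_distance(u, v)
        if dist < best:
            best = dist
    return best


@dataclass(frozen=True)
class ConstraintProfile:
    """The bundle of rules a tag set must satisfy.

    Parameters
    ----------
    d
        Minimum pairwise edit distance between distinct tags (>= 1).
    gc_mode
        ``"range"``: per-tag GC percentage within [gc_min, gc_max]
        (inclusive).  ``"fixed"``: exactly ``gc_fixed_count`` G/C bases per
        tag -- the stricter rule that pins all tags to one GC composition
        so their melting temperatures cluster tightly.  ``"off"``: no GC
        rule.
    gc_fixed_count
        G/C count for ``fixed`` mode; ``None`` means floor(n/2), resolved
        per tag length.
    continuity_max
        Cap on the longest homopolymer run within any tag (default 2).
    complementarity
        ``"none"``; ``"self"`` -- no tag may equal its own reverse
        complement; ``"cross"`` -- no tag may equal the reverse complement
        of *any* tag in the set (the self rule is the i == j case and is
        implied).
    """

    d: int = 3
    gc_mode: str = "range"  # {"range", "fixed", "off"}
    gc_min: float = 40.0
    gc_max: float = 60.0
    gc_fixed_count: int | None = None
    continuity_max: int = 2
    complementarity: str = "none"  # {"none", "self", "cross"}

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("minimum distance d must be >= 1")
        if self.gc_mode not in ("range", "fixed", "off"):
            raise ValueError(f"unknown gc_mode {self.gc_mode!r}")
        if self.complementarity not in ("none", "self", "cross"):
            raise ValueError(f"unknown complementarity mode {self.complementarity!r}")
        if not 0 <= self.gc_min <= self.gc_max <= 100:
            raise ValueError("need 0 <= gc_min <= gc_max <= 100")
        if self.gc_fixed_count is not None and self.gc_fixed_count < 0:
            raise ValueError("gc_fixed_count must be >= 0")
        if self.continuity_max < 1:
            raise ValueError("continuity_max must be >= 1")

    def fixed_count_for(self, n: int) -> int:
        """Resolved G/C count for tags of length ``n`` in fixed mode."""
        return self.gc_fixed_count if self.gc_fixed_count is not None else n // 2

    @property
    def excludes_self_complementary(self) -> bool:
        return self.complementarity in ("self", "cross")

    def check_feasible(self, n: int) -> None:
        """Raise ValueError for a profile no length-n tag can satisfy."""
        if self.d > n:
            raise ValueError(f"minimum distance d={self.d} exceeds tag length n={n}")
        if self.gc_mode == "fixed" and self.fixed_count_for(n) > n:
            raise ValueError(f"gc_fixed_count={self.fixed_count_for(n)} exceeds tag length n={n}")
        if self.gc_mode == "range":
            # at least one integer G/C count must fall inside the window
            lo = math.ceil(self.gc_min * n / 100 - 1e-9)
            hi = math.floor(self.gc_max * n / 100 + 1e-9)
            if lo > hi:
                raise ValueError(
                    f"no integer G/C count of a length-{n} tag lies in "
                    f"[{self.gc_min}%, {self.gc_max}%]"
                )


def gc_satisfied(u: str, profile: ConstraintProfile) -> bool:
    """Does tag ``u`` satisfy the profile's GC rule?"""
    u = canonicalize(u)
    if profile.gc_mode == "off":
        return True
    if profile.gc_mode == "fixed":
        return gc_count(u) == profile.fixed_count_for(len(u))
    return profile.gc_min <= gc_content(u) <= profile.gc_max


def continuity(members: Sequence[str]) -> int:
    """Maximum homopolymer-run length over all tags in the set."""
    members = list(members)
    if not members:
        raise EmptySetError("continuity is undefined for an empty set")
    return max(longest_run(u) for u in members)


def cross_complement_violations(members: Sequence[str]) -> list[tuple[str, str]]:
    """All ordered pairs (u, v), including u == v, with u == revcomp(v).

    An empty result means the set satisfies the perfect-complementarity
    constraint: no tag can hybridize with (the reverse complement of) any
    tag in the set, itself included.  Each unordered conflict is reported
    once, as the pair (u, v) with u at the earlier (or equal) position.
    """
    members = [canonicalize(u) for u in members]
    out: list[tuple[str, str]] = []
    for i, u in enumerate(members):
        for j in range(i, len(members)):
            if u == reverse_complement(members[j]):
                out.append((u, members[j]))
    return out


def _single_tag_reasons(u: str, profile: ConstraintProfile) -> list[str]:
    reasons = []
    if not gc_satisfied(u, profile):
        reasons.append("gc")
    if longest_run(u) > profile.continuity_max:
        reasons.append("continuity")
    if profile.excludes_self_complementary and is_self_complementary(u):
        reasons.append("self_complement")
    return reasons


def validate_tag(
    u: str, members: Sequence[str], profile: ConstraintProfile
) -> tuple[bool, list[str]]:
    """Check whether tag ``u`` may join the (already valid) set ``members``.

    Returns ``(ok, reasons)`` where ``reasons`` enumerates every violated
    rule: ``distance`` (TTE below d), ``gc``, ``continuity``,
    ``self_complement``, ``cross_complement``, ``duplicate``.
    """
    u = canonicalize(u)
    members = [canonicalize(v) for v in members]
    if members and len(u) != len(members[0]):
        raise LengthMismatchError(
            f"tag length {len(u)} differs from set length {len(members[0])}"
        )
    reasons = _single_tag_reasons(u, profile)
    if u in members:
        reasons.append("duplicate")
    elif tte(u, members) < profile.d:
        reasons.append("distance")
    if profile.complementarity == "cross":
        rc = reverse_complement(u)
        if any(v == rc or u == reverse_complement(v) for v in members):
            reasons.append("cross_complement")
    return (not reasons, reasons)


@dataclass
class ValidationReport:
    """Set-level audit produced by :func:`validate_set`."""

    size: int
    length: int
    min_pairwise_distance: float
    continuity: int
    gc_failures: list[str]
    self_complementary: list[str]
    cross_complement_pairs: list[tuple[str, str]]
    duplicates: list[str]
    passed: bool

    def as_dict(self) -> dict:
        return {
            "size": self.size,
            "length": self.length,
            "min_pairwise_distance": (
                None if self.min_pairwise_distance == INFINITY else self.min_pairwise_distance
            ),
            "continuity": self.continuity,
            "gc_failures": self.gc_failures,
            "self_complementary": self.self_complementary,
            "cross_complement_pairs": [list(p) for p in self.cross_complement_pairs],
            "duplicates": self.duplicates,
            "passed": self.passed,
        }


def validate_set(members: Sequence[str], profile: ConstraintProfile) -> ValidationReport:
    """Audit a tag set against a constraint profile.

    Checks every rule independently of how the set was produced; a set
    emitted by any designer in this package must pass under its own
    profile (the closure invariant).
    """
    members = [canonicalize(u) for u in members]
    if not members:
        raise EmptySetError("cannot validate an empty tag set")
    n = len(members[0])
    if any(len(u) != n for u in members):
        raise LengthMismatchError("tags of mixed lengths in one set")

    seen: set[str] = set()
    duplicates = [u for u in members if u in seen or seen.add(u)]  # type: ignore[func-returns-value]

    min_dist = INFINITY
    uniq = sorted(set(members))
    for i, u in enumerate(uniq):
        for v in uniq[i + 1 :]:
            dist = edit_distance(u, v)
            if dist < min_dist:
                min_dist = dist

    gc_failures = [u for u in uniq if not gc_satisfied(u, profile)]
    cont = continuity(members)
    selfc = (
        [u for u in uniq if is_self_complementary(u)]
        if profile.excludes_self_complementary
        else []
    )
    crossc = cross_complement_violations(uniq) if profile.complementarity == "cross" else []

    passed = (
        not duplicates
        and min_dist >= profile.d
        and not gc_failures
        and cont <= profile.continuity_max
        and not selfc
        and not crossc
    )
    return ValidationReport(
        size=len(members),
        length=n,
        min_pairwise_distance=min_dist,
        continuity=cont,
        gc_failures=gc_failures,
        self_complementary=selfc,
        cross_complement_pairs=crossc,
        duplicates=duplicates,
        passed=passed,
    )


@dataclass
class TagSet:
    """An ordered collection of same-length tags plus its profile."""

    tags: list[str] = field(default_factory=list)
    profile: ConstraintProfile = field(default_factory=ConstraintProfile)

    def __post_init__(self) -> None:
        self.tags = [canonicalize(u) for u in self.tags]
        if self.tags:
            n = len(self.tags[0])
            if any(len(u) != n for u in self.tags):
                raise LengthMismatchError("tags of mixed lengths in one set")

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self):
        return iter(self.tags)

    def __contains__(self, u: str) -> bool:
        return canonicalize(u) in self.tags

    @property
    def length(self) -> int | None:
        return len(self.tags[0]) if self.tags else None

    def validate(self) -> ValidationReport:
        return validate_set(self.tags, self.profile)

    def as_code_matrix(self) -> np.ndarray:
        """(m, n) uint8 matrix of the member sequences."""
        return np.stack([encode(u) for u in self.tags]) if self.tags else np.empty((0, 0), np.uint8)
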