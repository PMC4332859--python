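"""Nearest-neighbor melting temperatures and the Tm-gap set metric.

A multiplexed hybridization behaves uniformly only when all tags melt in a
narrow temperature window, so a tag set is scored by its *Tm gap*: the
spread ``|max Tm - min Tm|`` over its members.  Per-tag Tm follows the
two-state nearest-neighbor model: enthalpy and entropy are summed over
consecutive dinucleotide stacks plus duplex-initiation terms for the two
terminal base pairs, and

    Tm = dH_total / (dS_total + R ln(C_T / 4)) - 273.15

with dH in cal/mol, dS in cal/(mol K), R = 1.987 cal/(mol K), and C_T the
total strand concentration of a non-self-complementary duplex.  Entropy is
adjusted for monovalent salt by 0.368 (N-1) ln[Na+] with N the sequence
length.  The default parameter table is the unified oligonucleotide
DNA/DNA set shipped as ``data/nn_unified.json``; alternative tables can be
loaded from any JSON file with the same shape.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

from .constraints import EmptySetError
from .sequences import canonicalize, is_self_complementary, reverse_complement

GAS_CONSTANT = 1.987  # cal / (mol K)


class SequenceTooShortError(ValueError):
    """Raised for sequences shorter than one dinucleotide stack."""


def _load_table(source=None) -> dict:
    if source is None:
        ref = resources.files("tagforge.data") / "nn_unified.json"
        return json.loads(ref.read_text())
    with open(source) as fh:
        return json.load(fh)


@dataclass(frozen=True)
class ThermoModel:
    """Nearest-neighbor parameter table plus reaction conditions.

    ``nn_table`` maps each of the 10 unique Watson-Crick stacks (top-strand
    dinucleotide, 5'->3') to (dH kcal/mol, dS cal/(mol K)); ``initiation``
    maps terminal pair class ("GC"/"AT") to its initiation contribution.
    """

    nn_table: dict[str, tuple[float, float]]
    initiation: dict[str, tuple[float, float]]
    strand_concentration: float = 2.5e-7  # molar total strand (C_T)
    monovalent_salt: float = 0.05  # molar Na+
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if self.strand_concentration <= 0 or self.monovalent_salt <= 0:
            raise ValueError("strand concentration and salt must be positive")
        missing = _UNIQUE_STACKS - set(self.nn_table)
        if missing:
            raise ValueError(f"nn_table missing stacks: {sorted(missing)}")

    @classmethod
    def default(cls, strand_concentration: float | None = None,
                monovalent_salt: float | None = None) -> "ThermoModel":
        return cls.from_json(None, strand_concentration, monovalent_salt)

    @classmethod
    def from_json(cls, path=None, strand_concentration: float | None = None,
                  monovalent_salt: float | None = None) -> "ThermoModel":
        raw = _load_table(path)
        ct = strand_concentration or raw.get("defaults", {}).get(
            "strand_concentration_molar", 2.5e-7)
        na = monovalent_salt or raw.get("defaults", {}).get("monovalent_salt_molar", 0.05)
        return cls(
            nn_table={k: (v["dH"], v["dS"]) for k, v in raw["stacks"].items()},
            initiation={k: (v["dH"], v["dS"]) for k, v in raw["initiation"].items()},
            strand_concentration=ct,
            monovalent_salt=na,
        )

    def stack(self, dinuc: str) -> tuple[float, float]:
        """Parameters for any dinucleotide, resolving the reverse-complement
        symmetry (e.g. TG reads the CA entry: same duplex, other strand)."""
        if dinuc in self.nn_table:
            return self.nn_table[dinuc]
        return self.nn_table[reverse_complement(dinuc)]


_UNIQUE_STACKS = frozenset(
    ["AA", "AT", "TA", "CA", "GT", "CT", "GA", "CG", "GC", "GG"]
)


def melting_temperature(seq: str, model: ThermoModel | None = None) -> float:
    """Two-state nearest-neighbor Tm of ``seq`` with its perfect complement, in Celsius.

    Deterministic for a fixed model.  Invariant under reverse complement of
    the input (the duplex is the same molecule either way).  Warns if asked
    to score a self-complementary sequence, whose two-state factor would be
    C_T rather than C_T/4; valid tag sets never contain one.
    """
    s = canonicalize(seq)
    if len(s) < 2:
        raise SequenceTooShortError("Tm needs at least 2 bases (one stack)")
    model = model or ThermoModel.default()
    if is_self_complementary(s):
        warnings.warn(
            f"{s} is self-complementary; two-state C_T/4 form is an approximation",
            stacklevel=2,
        )
    dh = 0.0  # kcal/mol
    ds = 0.0  # cal/(mol K)
    for i in range(len(s) - 1):
        h, sv = model.stack(s[i : i + 2])
        dh += h
        ds += sv
    for terminal in (s[0], s[-1]):
        key = "GC" if terminal in "GC" else "AT"
        h, sv = model.initiation[key]
        dh += h
        ds += sv
    ds += 0.368 * (len(s) - 1) * math.log(model.monovalent_salt)
    tm_kelvin = (dh * 1000.0) / (
        ds + model.gas_constant * math.log(model.strand_concentration / 4.0)
    )
    return tm_kelvin - 273.15


def tm_gap(members: Sequence[str], model: ThermoModel | None = None) -> float:
    """Spread ``|max Tm - min Tm|`` over a tag set, in Celsius degrees.

    Zero for a singleton; never decreases when a tag is added.  Smaller is
    better: the tags hybridize uniformly at one annealing temperature.
    """
    members = list(members)
    if not members:
        raise EmptySetError("Tm gap is undefined for an empty set")
    model = model or ThermoModel.default()
    tms = [melting_temperature(u, model) for u in members]
    return max(tms) - min(tms)


@dataclass
class ThermoReport:
    """Per-tag Tm listing plus the set-level gap (CLI convenience)."""

    tms: dict[str, float] = field(default_factory=dict)
    gap: float = 0.0

    @classmethod
    def for_set(cls, members: Sequence[str], model: ThermoModel | None = None) -> "ThermoReport":
        model = model or ThermoModel.default()
        tms = {u: melting_temperature(u, model) for u in members}
        vals = list(tms.values())
        return cls(tms=tms, gap=(max(vals) - min(vals)) if vals else 0.0)
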