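"""Reading, writing, and synthesizing tag sets.

FASTA is the interchange format (tags are designed oligos, written 5'->3');
a bare one-sequence-per-line text format and a per-tag TSV report are also
supported.  Ambiguity codes are rejected on read: a tag must be a concrete
synthesizable word over {A, C, G, T}.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constraints import ConstraintProfile, LengthMismatchError, TagSet, validate_tag
from .sequences import canonicalize, gc_content, longest_run, reverse_complement
from .thermo import ThermoModel, melting_temperature


def read_tagset(
    path: str | Path,
    fmt: str = "auto",
    profile: ConstraintProfile | None = None,
    require_uniform_length: bool = True,
) -> TagSet:
    """Read a tag set from FASTA or line-oriented text.

    ``fmt="auto"`` treats files whose first non-blank character is ``>`` as
    FASTA.  Sequences are upcased; any non-ACGT character (including N and
    IUPAC ambiguity codes) is an error.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty input file")
    if fmt == "auto":
        fmt = "fasta" if text.lstrip().startswith(">") else "lines"
    if fmt == "fasta":
        seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    elif fmt == "lines":
        seqs = [line.strip() for line in text.splitlines() if line.strip()]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not seqs:
        raise ValueError(f"{path}: no sequences found")
    tags = [canonicalize(s) for s in seqs]
    if require_uniform_length and len({len(t) for t in tags}) > 1:
        raise LengthMismatchError(
            f"{path}: mixed tag lengths {sorted({len(t) for t in tags})}; "
            "a tag set must be uniform-length"
        )
    return TagSet(tags=tags, profile=profile or ConstraintProfile())


def write_tagset(
    tag_set: TagSet | Sequence[str],
    path: str | Path,
    fmt: str = "fasta",
    thermo_model: ThermoModel | None = None,
) -> Path:
    """Write a tag set as FASTA, plain lines, or a per-tag TSV report.

    FASTA records are named ``tag_0001`` onward.  The TSV report includes
    per-tag GC%, longest homopolymer run, and nearest-neighbor Tm.  Output
    is deterministic for a fixed input (no timestamps).
    """
    tags = list(tag_set.tags if isinstance(tag_set, TagSet) else tag_set)
    path = Path(path)
    if fmt == "fasta":
        records = [
            SeqRecord(Seq(t), id=f"tag_{i + 1:04d}", description="")
            for i, t in enumerate(tags)
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    elif fmt == "lines":
        path.write_text("".join(t + "\n" for t in tags))
    elif fmt == "tsv":
        model = thermo_model or ThermoModel.default()
        lines = ["name\tsequence\tgc_percent\tlongest_run\ttm_celsius"]
        for i, t in enumerate(tags):
            lines.append(
                f"tag_{i + 1:04d}\t{t}\t{gc_content(t):.2f}\t{longest_run(t)}"
                f"\t{melting_temperature(t, model):.4f}"
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def generate_fixture_set(
    n: int,
    m: int,
    profile: ConstraintProfile | None = None,
    seed: int = 0,
    enforce_distance: bool = False,
    plant_cross_complement: bool = False,
    max_attempts: int = 200_000,
) -> TagSet:
    """Rejection-sample a reproducible tag set for tests and demos.

    Samples random length-n words until ``m`` of them satisfy the
    profile's single-tag rules (GC, continuity, self-complementarity);
    with ``enforce_distance`` the pairwise distance rule is applied
    greedily as well.  ``plant_cross_complement`` appends the reverse
    complement of the first member, deliberately violating the
    cross-complementarity rule -- useful for tests that need a set failing
    exactly that check.
    """
    from .sequences import decode

    profile = profile or ConstraintProfile()
    profile.check_feasible(n)
    rng = np.random.default_rng(seed)
    tags: list[str] = []
    attempts = 0
    while len(tags) < m:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not sample {m} tags of length {n} under the profile "
                f"after {max_attempts} attempts"
            )
        cand = decode(rng.integers(0, 4, size=n, dtype=np.uint8))
        if enforce_distance:
            ok, _ = validate_tag(cand, tags, profile)
        else:
            from .constraints import _single_tag_reasons

            ok = not _single_tag_reasons(cand, profile) and cand not in tags
        if ok:
            tags.append(cand)
    if plant_cross_complement:
        tags.append(reverse_complement(tags[0]))
    return TagSet(tags=tags, profile=profile)
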