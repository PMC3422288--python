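"""Generation of repetitive target sequences.

A target region is built by concatenating ``unit_count`` copies of a single
repeat unit, with no linker sequence between units, mimicking a perfect
tandem array (e.g. a young tandem gene duplication).  Two modes exist:

* ``random_units`` — the unit itself is a uniform random sequence; all copies
  are byte-identical, which is the hardest case for short-read assembly.
* ``tandem_unit`` — a user-supplied unit (e.g. a gene of interest) is
  concatenated; optionally one "tracking" substitution is placed at a random
  position in every copy so that the recovered order/orientation of the units
  can be assessed after reconstruction.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import BASES, encode, random_dna
from .errors import ParameterError

#: default grid used in the unit length x unit count exploration
DEFAULT_UNIT_LENGTHS = tuple(range(4, 4001, 5))
DEFAULT_UNIT_COUNTS = tuple(range(4, 101, 4))
DEFAULT_MAX_TOTAL_BP = 30_000
DEFAULT_REPLICATES = 5


@dataclass(frozen=True)
class TargetSpec:
    """Recipe for one target sequence (one grid-cell replicate)."""

    unit_length: int
    unit_count: int
    mode: str = "random_units"  # "random_units" | "tandem_unit"
    tracking_mutation: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.unit_length < 1 or self.unit_count < 1:
            raise ParameterError("unit_length and unit_count must be >= 1")
        if self.mode not in ("random_units", "tandem_unit"):
            raise ParameterError(f"unknown target mode: {self.mode!r}")

    @property
    def total_length(self) -> int:
        return self.unit_length * self.unit_count


@dataclass
class TargetSequence:
    """An unmutated target region with known unit structure.

    ``unit_boundaries`` are half-open intervals tiling ``[0, len(sequence))``;
    ``tracking_positions`` holds ``(unit_index, offset)`` pairs for the
    tracking substitutions (empty unless requested).
    """

    sequence: str
    unit_boundaries: list[tuple[int, int]]
    tracking_positions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.sequence)
        pos = 0
        for start, end in self.unit_boundaries:
            if start != pos or end <= start:
                raise ParameterError("unit boundaries must tile the sequence")
            pos = end
        if pos != n:
            raise ParameterError("unit boundaries must tile the sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_units(self) -> int:
        return len(self.unit_boundaries)

    def unit(self, i: int) -> str:
        start, end = self.unit_boundaries[i]
        return self.sequence[start:end]


def generate_random_target(
    unit_length: int, unit_count: int, rng: np.random.Generator
) -> TargetSequence:
    """Draw one uniform random unit and concatenate ``unit_count`` copies.

    All copies are identical, giving a perfectly repetitive target.
    """
    if unit_length < 1 or unit_count < 1:
        raise ParameterError("unit_length and unit_count must be >= 1")
    unit = random_dna(unit_length, rng)
    boundaries = [(i * unit_length, (i + 1) * unit_length) for i in range(unit_count)]
    return TargetSequence(unit * unit_count, boundaries)


def generate_tandem_target(
    unit_sequence: str,
    copies: int,
    tracking: bool,
    rng: np.random.Generator,
) -> TargetSequence:
    """Concatenate ``copies`` of a supplied unit, optionally adding one
    tracking substitution per copy at an independent random position."""
    if copies < 1:
        raise ParameterError("copies must be >= 1")
    if not unit_sequence:
        raise ParameterError("unit sequence must be non-empty")
    encode(unit_sequence)  # validates the alphabet (rejects ambiguity codes)
    unit_sequence = unit_sequence.upper()
    L = len(unit_sequence)
    seq = list(unit_sequence * copies)
    tracking_positions: list[tuple[int, int]] = []
    if tracking:
        for i in range(copies):
            off = int(rng.integers(0, L))
            old = seq[i * L + off]
            choices = [b for b in BASES if b != old]
            seq[i * L + off] = choices[int(rng.integers(0, 3))]
            tracking_positions.append((i, off))
    boundaries = [(i * L, (i + 1) * L) for i in range(copies)]
    return TargetSequence("".join(seq), boundaries, tracking_positions)


def from_spec(spec: TargetSpec, unit_sequence: str | None = None) -> TargetSequence:
    """Materialize a :class:`TargetSpec` (seeded, hence reproducible)."""
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "random_units":
        if spec.tracking_mutation:
            unit = random_dna(spec.unit_length, rng)
            return generate_tandem_target(unit, spec.unit_count, True, rng)
        return generate_random_target(spec.unit_length, spec.unit_count, rng)
    if unit_sequence is None:
        unit_sequence = random_dna(spec.unit_length, rng)
    elif len(unit_sequence) != spec.unit_length:
        raise ParameterError("unit_sequence length does not match the spec")
    return generate_tandem_target(
        unit_sequence, spec.unit_count, spec.tracking_mutation, rng
    )


def grid_specs(
    unit_lengths: Iterable[int] = DEFAULT_UNIT_LENGTHS,
    unit_counts: Iterable[int] = DEFAULT_UNIT_COUNTS,
    max_total_bp: int = DEFAULT_MAX_TOTAL_BP,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> list[TargetSpec]:
    """Enumerate replicate specs for every (length, count) cell whose total
    length does not exceed ``max_total_bp``.

    Each replicate receives its own seed derived deterministically from
    ``seed``, so the unit sequence is re-randomized per replicate.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for length in unit_lengths:
        for count in unit_counts:
            if length * count > max_total_bp:
                continue
            for _ in range(replicates):
                specs.append(
                    TargetSpec(
                        unit_length=length,
                        unit_count=count,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                )
    return specs


def write_fasta(target: TargetSequence, path: str | Path, name: str = "target") -> None:
    """Write the target as FASTA plus a sidecar TSV of unit structure.

    The sidecar (``<path>.units.tsv``) has one row per unit: unit index,
    start, end and (if present) the offset of the tracking substitution.
    """
    record = SeqRecord(Seq(target.sequence), id=name, description="")
    SeqIO.write([record], str(path), "fasta")
    tracking = dict(target.tracking_positions)
    with open(f"{path}.units.tsv", "w") as fh:
        fh.write("unit\tstart\tend\ttracking_offset\n")
        for i, (start, end) in enumerate(target.unit_boundaries):
            off = tracking.get(i, "")
            fh.write(f"{i}\t{start}\t{end}\t{off}\n")


def read_unit_fasta(path: str | Path) -> str:
    """Read the first record of a FASTA file as a repeat-unit sequence."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()
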