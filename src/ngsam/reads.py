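"""Paired-end short-read simulation of the weighted mutant pool.

Library construction is modelled as independent random fragmentation of
each mutant: fragment lengths are log-normal (arithmetic mean 400 bp,
coefficient of variation 0.055 by default, implying a mean insert of
400 - 2*101 = 198 bp between the two 101-bp reads), start positions are
uniform, and the sequenced strand is random.  Read 2 is the reverse
complement of the fragment's far end.  Sequencing errors are substitutions
drawn from a simple position-dependent model: the per-base error rate ramps
linearly along the read (quality degrades toward the 3' end, as on real
short-read instruments), and the emitted quality string is the Phred
encoding of the model's per-position rate.

The number of fragments per mutant is proportional to its final-PCR
descendant count, so amplification fluctuations carry through to coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from ._seq import decode, encode
from .errors import ParameterError
from .mutagenesis import MutantPool

DEFAULT_READ_LENGTH = 101
DEFAULT_TOTAL_COVERAGE = 4000.0


@dataclass(frozen=True)
class FragmentModel:
    """Log-normal fragment length model.

    ``mean_length`` and ``cv`` are the *natural-scale* arithmetic mean and
    coefficient of variation; the underlying normal parameters are
    ``sigma^2 = ln(1 + cv^2)`` and ``mu = ln(mean) - sigma^2 / 2``.
    """

    mean_length: float = 400.0
    cv: float = 0.055

    def __post_init__(self):
        if self.mean_length <= 0 or self.cv <= 0:
            raise ParameterError("mean_length and cv must be positive")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(np.log1p(self.cv**2)))

    @property
    def mu(self) -> float:
        return float(np.log(self.mean_length) - self.sigma**2 / 2)

    def mean_insert(self, read_length: int = DEFAULT_READ_LENGTH) -> float:
        """Mean unsequenced gap between the two mates."""
        return self.mean_length - 2 * read_length

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.rint(rng.lognormal(self.mu, self.sigma, size=n)).astype(int)


@dataclass(frozen=True)
class ErrorModel:
    """Position-ramped substitution error model.

    The error rate at read position i is linear from ``rate_start`` (5' end)
    to ``rate_end`` (3' end); ``flat(rate)`` gives a uniform alternative.
    """

    rate_start: float = 0.001
    rate_end: float = 0.01

    def __post_init__(self):
        if not (0 <= self.rate_start <= 1 and 0 <= self.rate_end <= 1):
            raise ParameterError("error rates must lie in [0, 1]")

    @classmethod
    def flat(cls, rate: float) -> "ErrorModel":
        return cls(rate_start=rate, rate_end=rate)

    @classmethod
    def perfect(cls) -> "ErrorModel":
        return cls(rate_start=0.0, rate_end=0.0)

    def rates(self, read_length: int) -> np.ndarray:
        return np.linspace(self.rate_start, self.rate_end, read_length)

    def quality_string(self, read_length: int) -> str:
        """Phred+33 qualities matching the per-position model rates."""
        r = np.clip(self.rates(read_length), 1e-5, 0.75)
        q = np.clip(np.rint(-10 * np.log10(r)), 2, 41).astype(int)
        return "".join(chr(33 + v) for v in q)


@dataclass
class ReadPair:
    """One simulated read pair with full provenance."""

    read1: str
    read2: str
    qual1: str
    qual2: str
    mutant_id: int
    fragment_start: int
    fragment_length: int
    strand: str  # '+' fragment on mutant forward strand, '-' reverse


def allocate_coverage(
    pool: MutantPool,
    total_coverage: float = DEFAULT_TOTAL_COVERAGE,
    target_length: int | None = None,
    read_length: int = DEFAULT_READ_LENGTH,
) -> np.ndarray:
    """Number of read pairs per mutant so total sequenced bases equal
    ``total_coverage * target_length``, split proportionally to final-PCR
    descendant weights (largest-remainder rounding, deterministic)."""
    if len(pool) == 0:
        raise ParameterError("mutant pool is empty")
    if total_coverage <= 0:
        raise ParameterError("total_coverage must be positive")
    if target_length is None:
        target_length = len(pool.sequences[0])
    total_pairs = int(round(total_coverage * target_length / (2 * read_length)))
    w = np.asarray(pool.weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones(len(pool))
    quota = total_pairs * w / w.sum()
    counts = np.floor(quota).astype(int)
    remainder = total_pairs - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:remainder]] += 1
    return counts


def fragment_and_sequence(
    pool: MutantPool,
    pair_counts: np.ndarray | Iterable[int],
    rng: np.random.Generator,
    fragment_model: FragmentModel | None = None,
    read_length: int = DEFAULT_READ_LENGTH,
    error_model: ErrorModel | None = None,
    max_redraws: int = 100,
) -> Iterator[ReadPair]:
    """Yield read pairs for every mutant.

    Fragment lengths shorter than the read length are redrawn (no adapter
    read-through is modelled); lengths exceeding the molecule are redrawn
    too, falling back to the full molecule after ``max_redraws``.
    """
    fragment_model = fragment_model or FragmentModel()
    error_model = error_model or ErrorModel()
    rates = error_model.rates(read_length)
    qual = error_model.quality_string(read_length)
    pair_counts = np.asarray(list(pair_counts), dtype=int)
    if len(pair_counts) != len(pool):
        raise ParameterError("need one pair count per mutant")

    for mid, (seq, n_pairs) in enumerate(zip(pool.sequences, pair_counts)):
        L = len(seq)
        if L < read_length:
            raise ParameterError(
                f"mutant {mid} is shorter ({L}) than the read length"
            )
        arr = encode(seq)
        arr_rc = 3 - arr[::-1]  # complement in integer code
        for _ in range(int(n_pairs)):
            flen = 0
            for _try in range(max_redraws):
                flen = int(fragment_model.sample(1, rng)[0])
                if read_length <= flen <= L:
                    break
            else:
                flen = L
            start = int(rng.integers(0, L - flen + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                frag = arr[start : start + flen]
            else:
                frag = arr_rc[L - start - flen : L - start]
            r1 = frag[:read_length].copy()
            r2 = (3 - frag[-read_length:][::-1]).copy()
            for r in (r1, r2):
                hit = np.nonzero(rng.random(read_length) < rates)[0]
                if hit.size:
                    shift = rng.integers(1, 4, size=hit.size).astype(np.uint8)
                    r[hit] = (r[hit] + shift) % 4
            yield ReadPair(
                read1=decode(r1),
                read2=decode(r2),
                qual1=qual,
                qual2=qual,
                mutant_id=mid,
                fragment_start=start,
                fragment_length=flen,
                strand=strand,
            )


def simulate_reads(
    pool: MutantPool,
    rng: np.random.Generator,
    total_coverage: float = DEFAULT_TOTAL_COVERAGE,
    target_length: int | None = None,
    fragment_model: FragmentModel | None = None,
    read_length: int = DEFAULT_READ_LENGTH,
    error_model: ErrorModel | None = None,
) -> list[ReadPair]:
    """Convenience wrapper: allocate coverage, then fragment and sequence."""
    counts = allocate_coverage(pool, total_coverage, target_length, read_length)
    return list(
        fragment_and_sequence(
            pool, counts, rng, fragment_model, read_length, error_model
        )
    )


def write_fastq(
    pairs: Iterable[ReadPair],
    path1: str | Path,
    path2: str | Path,
    provenance_tsv: str | Path | None = None,
) -> int:
    """Write index-synchronized paired FASTQ files (Phred+33).

    Optionally writes a provenance TSV (read id, mutant id, fragment
    interval, strand).  Returns the number of pairs written.
    """
    n = 0
    prov = open(provenance_tsv, "w") if provenance_tsv else None
    try:
        if prov:
            prov.write("read_id\tmutant_id\tstart\tend\tstrand\n")
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for i, p in enumerate(pairs):
                rid = f"sim.{i}"
                f1.write(f"@{rid}/1\n{p.read1}\n+\n{p.qual1}\n")
                f2.write(f"@{rid}/2\n{p.read2}\n+\n{p.qual2}\n")
                if prov:
                    prov.write(
                        f"{rid}\t{p.mutant_id}\t{p.fragment_start}\t"
                        f"{p.fragment_start + p.fragment_length}\t{p.strand}\n"
                    )
                n += 1
    finally:
        if prov:
            prov.close()
    return n
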