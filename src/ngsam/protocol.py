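"""Orchestration of the NG-SAM protocol stages.

The protocol chains three PCRs and two dilutions::

    S0 --mutagenic PCR (n1)--> S1 --dilute d1--> S2
       --cleanup PCR (n2)-->   S3 --dilute d2--> S4
       --final PCR (n3)-->     S5

Mutations are introduced only in the mutagenic PCR; the cleanup PCR merely
amplifies (it exists, in the wet protocol, to wash out base analogues), and
the final PCR amplifies each second-dilution molecule to sequencing
quantity.  Only the lineages of the S4 sampled molecules matter, so the
mutagenic genealogy is simulated backward for the distinct cleanup-PCR
founders of those molecules rather than for the whole pool.

Dilutions are Poisson samples with mean ``count / factor``; a dilution
factor of exactly 1 means no dilution is performed (the whole solution is
carried over, keeping the exact count).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigurationError, ParameterError, ProtocolFailure
from .mutagenesis import MutantPool, SubstitutionModel, mutate_pool
from .pcr import PCRParams, sample_genealogy, simulate_counts


@dataclass(frozen=True)
class ProtocolParams:
    """Protocol parameters; defaults are the tuned reference conditions."""

    s0: int = 5000
    n1: int = 20
    d1: float = 70_000.0
    n2: int = 20
    d2: float = 16_000_000.0
    n3: int = 30
    efficiency: float = 0.75
    genealogy_sample_cap: int = 200

    def __post_init__(self):
        if self.s0 < 1:
            raise ParameterError("s0 must be >= 1")
        if min(self.n1, self.n2, self.n3) < 0:
            raise ParameterError("cycle counts must be >= 0")
        if min(self.d1, self.d2) < 1:
            raise ParameterError("dilution factors must be >= 1")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ParameterError("efficiency must lie in [0, 1]")

    def pcr(self, stage: int, n_start: int) -> PCRParams:
        n_cycles = {1: self.n1, 2: self.n2, 3: self.n3}[stage]
        return PCRParams(n_start=n_start, efficiency=self.efficiency, n_cycles=n_cycles)


@dataclass
class StageCounts:
    """Molecule counts at every protocol stage (realized or expected)."""

    s0: float
    s1: float
    s2: float
    s3: float
    s4: float
    s5: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def dilute(count: int, factor: float, rng: np.random.Generator) -> int:
    """Sample the molecule count surviving a dilution: Poisson with mean
    ``count / factor``.  Factor 1 is the identity (no dilution step)."""
    if count < 0:
        raise ParameterError("count must be >= 0")
    if factor < 1:
        raise ParameterError("dilution factor must be >= 1")
    if count == 0:
        return 0
    if factor == 1:
        return int(count)
    return int(rng.poisson(count / factor))


def expected_stage_counts(params: ProtocolParams) -> StageCounts:
    """Deterministic expectation chain used for tuning the dilutions."""
    g = 1.0 + params.efficiency
    s1 = params.s0 * g**params.n1
    s2 = s1 / params.d1
    s3 = s2 * g**params.n2
    s4 = s3 / params.d2
    s5 = s4 * g**params.n3
    return StageCounts(float(params.s0), s1, s2, s3, s4, s5)


def simulate_stage_counts(
    params: ProtocolParams, rng: np.random.Generator
) -> StageCounts:
    """Counts-only protocol realization (no genealogy, no sequences).

    Never raises on an empty sample; downstream stages are reported as 0.
    """
    s1 = simulate_counts(params.pcr(1, params.s0), rng).final_count
    s2 = min(dilute(s1, params.d1, rng), s1)
    if s2 == 0:
        return StageCounts(params.s0, s1, 0, 0, 0, 0)
    s3 = simulate_counts(params.pcr(2, s2), rng).final_count
    s4 = min(dilute(s3, params.d2, rng), s3)
    if s4 == 0:
        return StageCounts(params.s0, s1, s2, s3, 0, 0)
    s5 = simulate_counts(params.pcr(3, s4), rng).final_count
    return StageCounts(params.s0, s1, s2, s3, s4, s5)


def run_protocol(
    target,
    params: ProtocolParams,
    model: SubstitutionModel,
    rng: np.random.Generator,
) -> tuple[MutantPool, StageCounts]:
    """Run the full protocol on a target, returning the weighted mutant pool
    and the realized stage counts.

    ``target`` may be a DNA string or any object with a ``sequence``
    attribute.  Raises :class:`ProtocolFailure` when a dilution leaves no
    molecules and :class:`ConfigurationError` when the number of sampled
    molecules exceeds ``genealogy_sample_cap``.
    """
    template = getattr(target, "sequence", target)

    pcr1 = params.pcr(1, params.s0)
    traj1 = simulate_counts(pcr1, rng)
    s1 = traj1.final_count
    s2 = min(dilute(s1, params.d1, rng), s1)
    if s2 == 0:
        raise ProtocolFailure("no molecules left after the first dilution")

    pcr2 = params.pcr(2, s2)
    traj2 = simulate_counts(pcr2, rng)
    s3 = traj2.final_count
    s4 = min(dilute(s3, params.d2, rng), s3)
    if s4 == 0:
        raise ProtocolFailure("no molecules left after the second dilution")
    if s4 > params.genealogy_sample_cap:
        raise ConfigurationError(
            f"sampled molecules ({s4}) exceed genealogy_sample_cap "
            f"({params.genealogy_sample_cap}); raise the cap to proceed"
        )

    # cleanup PCR is mutation-free: its genealogy only assigns each sampled
    # molecule to its founding S2 ancestor (relatedness through PCR2)
    gen2 = sample_genealogy(pcr2, s4, traj2, rng)
    s2_ancestors = gen2.leaf_founders()
    distinct = np.unique(s2_ancestors)
    type_of = {int(a): t for t, a in enumerate(distinct)}

    # mutagenic genealogy + mutations only for those distinct ancestors
    gen1 = sample_genealogy(pcr1, len(distinct), traj1, rng)
    base_pool = mutate_pool(gen1, template, model, rng)

    multiplicities = [0] * len(distinct)
    weights = [0] * len(distinct)
    s5 = 0
    for anc in s2_ancestors:
        t = type_of[int(anc)]
        multiplicities[t] += 1
        # independent final-PCR branching process per sampled molecule
        desc = simulate_counts(params.pcr(3, 1), rng).final_count
        weights[t] += desc
        s5 += desc

    pool = MutantPool(
        sequences=base_pool.sequences,
        founders=base_pool.founders,
        multiplicities=multiplicities,
        weights=weights,
    )
    counts = StageCounts(params.s0, s1, s2, s3, s4, s5)
    return pool, counts
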