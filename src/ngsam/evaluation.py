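"""Scoring of reconstructions and the two simulation-study grids.

An experiment is *successful* when every pipeline stage completed and the
called consensus aligned unambiguously to the target; success then comes
with three metrics: percent identity of the aligned portion, percent of the
target length recovered, and their product, the percent of correctly
reconstructed bases.  Failures are recorded with the stage at which they
occurred (empty sample after a dilution, assembly, contig strandedness,
ambiguous final alignment) and never abort a grid.

Two study designs are provided: setting 1 sweeps the repeat structure (unit
length x unit count) under fixed protocol parameters; setting 2 fixes a
tandem-duplication target (three copies of a gene-sized unit, with one
tracking substitution per copy) and sweeps the two dilution factors.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._align import align_infix
from ._seq import random_dna, revcomp
from .assembly import (
    DEFAULT_K,
    DEFAULT_MAX_DIVERGENCE,
    DEFAULT_MIN_CONTIG,
    DEFAULT_MIN_ORIENT_IDENTITY,
    reconstruct_consensus,
)
from .errors import (
    AssemblyFailure,
    ConfigurationError,
    ProtocolFailure,
    StrandednessFailure,
)
from .mutagenesis import SubstitutionModel
from .protocol import ProtocolParams, run_protocol
from .reads import DEFAULT_TOTAL_COVERAGE, ErrorModel, FragmentModel, simulate_reads
from .targets import TargetSequence, TargetSpec, from_spec, generate_tandem_target

#: margin by which the best consensus-vs-target alignment must beat the
#: runner-up (alternative orientation) to count as unambiguous
DEFAULT_AMBIGUITY_MARGIN = 1.1


@dataclass
class ExperimentResult:
    """Outcome of one simulated experiment."""

    success: bool
    failure_stage: str  # none|empty_sample|assembly|strandedness|alignment_ambiguous|config_cap
    pct_identity: float | None = None
    pct_length: float | None = None
    pct_correct: float | None = None
    n_mutant_types: int | None = None
    n_contigs: int | None = None
    tracking_recovered: float | None = None  # fraction of tracked units
    seed: int | None = None
    params: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)


def evaluate(
    consensus: str,
    target,
    ambiguity_margin: float = DEFAULT_AMBIGUITY_MARGIN,
) -> ExperimentResult:
    """Align the consensus to the target and score the reconstruction.

    The consensus is aligned in both orientations; the best alignment must
    beat the runner-up by ``ambiguity_margin`` in matched bases, otherwise
    the experiment fails as ``alignment_ambiguous``.  Identity is computed
    over the aligned portion only; recovered length is the aligned target
    span over the target length.
    """
    target_seq = getattr(target, "sequence", target)
    if not consensus or not target_seq:
        raise ValueError("consensus and target must be non-empty")
    fwd = align_infix(consensus, target_seq)
    rev = align_infix(revcomp(consensus), target_seq)
    best, runner = (fwd, rev) if fwd.matches >= rev.matches else (rev, fwd)
    if best.matches < ambiguity_margin * max(runner.matches, 1):
        return ExperimentResult(success=False, failure_stage="alignment_ambiguous")
    pct_identity = 100.0 * best.column_identity
    span = best.target_end - best.target_start + 1
    pct_length = 100.0 * span / len(target_seq)
    return ExperimentResult(
        success=True,
        failure_stage="none",
        pct_identity=pct_identity,
        pct_length=pct_length,
        pct_correct=pct_identity * pct_length / 100.0,
    )


def tracking_recovery(consensus: str, target: TargetSequence) -> float | None:
    """Fraction of tracking substitutions recovered in the consensus.

    Tracking mutations are never used by the assembler; they only report
    whether each repeat unit was recovered in place.  The consensus is
    aligned to the target (better orientation) and the consensus base over
    every tracked target position is compared to the target base there.
    """
    if not getattr(target, "tracking_positions", None):
        return None
    fwd = align_infix(consensus, target.sequence)
    rev = align_infix(revcomp(consensus), target.sequence)
    best, seq = (fwd, consensus) if fwd.matches >= rev.matches else (rev, revcomp(consensus))
    # map target position -> consensus base along the alignment path
    base_at: dict[int, str] = {}
    tpos, qpos = best.target_start, 0
    for n, op in best.cigar:
        if op in ("=", "X", "M"):
            for _ in range(n):
                base_at[tpos] = seq[qpos]
                tpos += 1
                qpos += 1
        elif op == "D":
            tpos += n
        elif op == "I":
            qpos += n
    hits = 0
    for unit_idx, offset in target.tracking_positions:
        start, _end = target.unit_boundaries[unit_idx]
        pos = start + offset
        if base_at.get(pos) == target.sequence[pos]:
            hits += 1
    return hits / len(target.tracking_positions)


def run_single_experiment(
    target: TargetSequence | str,
    protocol_params: ProtocolParams,
    model: SubstitutionModel,
    seed: int | np.random.SeedSequence,
    total_coverage: float = DEFAULT_TOTAL_COVERAGE,
    fragment_model: FragmentModel | None = None,
    error_model: ErrorModel | None = None,
    k: int = DEFAULT_K,
    min_contig: int = DEFAULT_MIN_CONTIG,
    max_divergence: float = DEFAULT_MAX_DIVERGENCE,
    min_orient_identity: float = DEFAULT_MIN_ORIENT_IDENTITY,
    ambiguity_margin: float = DEFAULT_AMBIGUITY_MARGIN,
    backend: str = "builtin",
) -> ExperimentResult:
    """Run one full NG-SAM experiment: protocol, sequencing, assembly,
    consensus, evaluation.

    All stage randomness derives from ``seed`` through independent child
    streams, so a result is reproducible from its seed alone.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_protocol, rng_reads = (np.random.default_rng(c) for c in ss.spawn(2))
    seed_val = int(ss.entropy) if isinstance(ss.entropy, int) else None
    echo = {"coverage": total_coverage, "k": k, **vars(protocol_params).copy()} \
        if hasattr(protocol_params, "__dict__") else {}
    timings: dict[str, float] = {}

    def fail(stage: str, n_types=None, n_contigs=None) -> ExperimentResult:
        return ExperimentResult(
            success=False, failure_stage=stage, n_mutant_types=n_types,
            n_contigs=n_contigs, seed=seed_val, params=echo, timings=timings,
        )

    t0 = time.perf_counter()
    try:
        pool, counts = run_protocol(target, protocol_params, model, rng_protocol)
    except ProtocolFailure:
        return fail("empty_sample")
    except ConfigurationError:
        return fail("config_cap")
    timings["protocol"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    target_seq = getattr(target, "sequence", target)
    reads = simulate_reads(
        pool, rng_reads, total_coverage, len(target_seq),
        fragment_model, error_model=error_model,
    )
    timings["sequencing"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        consensus, contigs = reconstruct_consensus(
            reads, k=k, min_contig=min_contig, max_divergence=max_divergence,
            min_identity=min_orient_identity, backend=backend,
        )
    except AssemblyFailure:
        return fail("assembly", n_types=int(counts.s4))
    except StrandednessFailure:
        return fail("strandedness", n_types=int(counts.s4))
    timings["assembly"] = time.perf_counter() - t0

    result = evaluate(consensus, target_seq, ambiguity_margin)
    if result.success and isinstance(target, TargetSequence):
        result.tracking_recovered = tracking_recovery(consensus, target)
    result.n_mutant_types = int(counts.s4)
    result.n_contigs = len(contigs)
    result.seed = seed_val
    result.params = echo
    result.timings = timings
    return result


def _result_row(res: ExperimentResult, **extra) -> dict:
    return {
        **extra,
        "success": res.success,
        "failure_stage": res.failure_stage,
        "pct_identity": res.pct_identity,
        "pct_length": res.pct_length,
        "pct_correct": res.pct_correct,
        "n_mutant_types": res.n_mutant_types,
        "n_contigs": res.n_contigs,
    }


def run_setting1(
    specs: Sequence[TargetSpec],
    protocol_params: ProtocolParams,
    model: SubstitutionModel,
    master_seed: int = 0,
    **experiment_kwargs,
) -> pd.DataFrame:
    """Simulate one experiment per target spec (unit length x count grid).

    Per-experiment seeds derive from ``master_seed`` via SeedSequence spawn
    keys indexed by position in ``specs``; reruns are byte-identical.
    """
    rows = []
    for i, spec in enumerate(specs):
        target = from_spec(spec)
        ss = np.random.SeedSequence(master_seed, spawn_key=(i,))
        res = run_single_experiment(target, protocol_params, model, ss, **experiment_kwargs)
        rows.append(
            _result_row(
                res,
                unit_length=spec.unit_length,
                unit_count=spec.unit_count,
                target_seed=spec.seed,
                experiment=i,
            )
        )
    return pd.DataFrame(rows)


def run_setting2(
    d1_values: Iterable[float],
    d2_values: Iterable[float],
    protocol_params: ProtocolParams,
    model: SubstitutionModel,
    target: TargetSequence | None = None,
    unit_length: int = 3813,
    unit_count: int = 3,
    replicates: int = 5,
    master_seed: int = 0,
    **experiment_kwargs,
) -> pd.DataFrame:
    """Sweep the two dilution factors on a fixed tandem-duplication target.

    The default target is ``unit_count`` concatenated copies of one random
    ``unit_length``-bp unit with a tracking substitution in every copy; all
    other parameters stay at ``protocol_params``.
    """
    if target is None:
        rng = np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(1,)))
        unit = random_dna(unit_length, rng)
        target = generate_tandem_target(unit, unit_count, True, rng)
    rows = []
    i = 0
    for d1 in d1_values:
        for d2 in d2_values:
            params = replace(protocol_params, d1=float(d1), d2=float(d2))
            for rep in range(replicates):
                ss = np.random.SeedSequence(master_seed, spawn_key=(2, i))
                res = run_single_experiment(target, params, model, ss, **experiment_kwargs)
                rows.append(_result_row(res, d1=d1, d2=d2, replicate=rep, experiment=i))
                i += 1
    return pd.DataFrame(rows)


def summarize_grid(df: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Per-cell summary: replicate count, % success, mean metrics among
    successes and mean number of mutant types."""
    def agg(group: pd.DataFrame) -> pd.Series:
        ok = group[group["success"]]
        return pd.Series(
            {
                "n": len(group),
                "pct_success": 100.0 * len(ok) / len(group),
                "mean_pct_identity": ok["pct_identity"].mean(),
                "mean_pct_length": ok["pct_length"].mean(),
                "mean_pct_correct": ok["pct_correct"].mean(),
                "mean_n_mutant_types": ok["n_mutant_types"].mean(),
            }
        )

    return df.groupby(by, as_index=False).apply(agg, include_groups=False)
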