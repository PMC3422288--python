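"""De novo assembly of pooled mutant reads and consensus reconstruction.

The builtin assembler is a deliberately simple de Bruijn graph
implementation tailored to the pooled-mutant setting: a long k-mer (90 by
default, against 101-bp reads) buys specificity at the cost of coverage;
low-multiplicity k-mers (sequencing errors) are filtered; short low-coverage
dead-end paths are clipped; and "bubbles" -- parallel paths between the same
two graph nodes -- are merged only when the paths diverge by at most
``max_divergence``, so distinct mutant types (which diverge far more) are
kept as separate contigs while residual error bubbles collapse.  K-mers are
counted for each read and its reverse complement, so every mutant yields its
contig on both strands; the orientation step folds them onto one strand.

Consensus reconstruction follows the contig route: contigs are oriented
against the longest contig, multiple-aligned by a center-star procedure
seeded on the longest contig, and reduced to a per-column majority-vote
consensus.

External-tool adapters (Velvet for assembly, muscle for MSA) are provided
behind the same interface for fidelity runs when the binaries are on PATH;
the builtin backends are the default.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._align import align_infix, divergence
from ._seq import revcomp
from .errors import AssemblyFailure, ParameterError, StrandednessFailure

DEFAULT_K = 90
DEFAULT_MIN_CONTIG = 400
DEFAULT_MAX_DIVERGENCE = 0.1
DEFAULT_MIN_ORIENT_IDENTITY = 0.70


@dataclass
class Contig:
    id: str
    sequence: str
    coverage: float = 0.0

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ContigSet:
    contigs: list[Contig]
    backend: str = "builtin"

    def __len__(self) -> int:
        return len(self.contigs)

    def longest(self) -> Contig:
        return max(self.contigs, key=len)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.contigs:
                fh.write(f">{c.id} cov={c.coverage:.1f}\n{c.sequence}\n")


@dataclass
class OrientedContig:
    id: str
    sequence: str  # on the strand of the longest contig
    flipped: bool
    identity: float  # identity of its alignment to the longest contig


@dataclass
class OrientedSet:
    """Contigs expressed on the strand of the longest contig (entry 0)."""

    contigs: list[OrientedContig]

    def __len__(self) -> int:
        return len(self.contigs)


def _read_sequences(reads) -> list[str]:
    seqs: list[str] = []
    for r in reads:
        if isinstance(r, str):
            seqs.append(r)
        else:  # ReadPair
            seqs.append(r.read1)
            seqs.append(r.read2)
    return seqs


def _count_kmers(seqs: list[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = defaultdict(int)
    for s in seqs:
        for strand in (s, revcomp(s)):
            for i in range(len(strand) - k + 1):
                counts[strand[i : i + k]] += 1
    return counts


def _weighted_median_count(counts: dict[str, int]) -> int:
    """Count-weighted median k-mer multiplicity.

    Error k-mers are numerous but carry little count mass, so this sits at
    the multiplicity of a typical *true* k-mer and estimates the realized
    per-type k-mer coverage.
    """
    order = np.sort(np.fromiter(counts.values(), dtype=np.int64))
    cum = np.cumsum(order)
    return int(order[np.searchsorted(cum, cum[-1] / 2)])


def _auto_cutoff(counts: dict[str, int]) -> int:
    """10% of the estimated per-type k-mer coverage, floor 2."""
    return max(2, int(round(0.1 * _weighted_median_count(counts))))


def _build_unitigs(
    counts: dict[str, int], k: int
) -> list[tuple[str, float, str, str]]:
    """Maximal unambiguous paths: (sequence, mean coverage, start node,
    end node) with nodes being (k-1)-mers."""
    outs: dict[str, list[str]] = defaultdict(list)
    ins: dict[str, list[str]] = defaultdict(list)
    for km in counts:
        outs[km[:-1]].append(km)
        ins[km[1:]].append(km)

    def simple(node: str) -> bool:
        return len(outs.get(node, ())) == 1 and len(ins.get(node, ())) == 1

    unitigs = []
    used: set[str] = set()
    for km in counts:
        if km in used:
            continue
        if simple(km[:-1]):
            continue  # interior of a path; reached from its start
        # km starts a unitig
        path = [km]
        used.add(km)
        cur = km
        while True:
            node = cur[1:]
            if not simple(node):
                break
            nxt = outs[node][0]
            if nxt in used:
                break
            path.append(nxt)
            used.add(nxt)
            cur = nxt
        seq = path[0] + "".join(p[-1] for p in path[1:])
        cov = float(np.mean([counts[p] for p in path]))
        unitigs.append((seq, cov, path[0][:-1], path[-1][1:]))
    # isolated cycles: every node simple, never started above
    for km in counts:
        if km in used:
            continue
        path = [km]
        used.add(km)
        cur = km
        while True:
            nxt = outs[cur[1:]][0]
            if nxt in used:
                break
            path.append(nxt)
            used.add(nxt)
            cur = nxt
        seq = path[0] + "".join(p[-1] for p in path[1:])
        cov = float(np.mean([counts[p] for p in path]))
        unitigs.append((seq, cov, path[0][:-1], path[-1][1:]))
    return unitigs


def _unitig_kmers(seq: str, k: int) -> list[str]:
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def _purge_low_coverage(
    counts: dict[str, int], k: int, ref_cov: float
) -> dict[str, int]:
    """Remove short unitigs whose coverage is far below the typical true
    k-mer coverage: error tips hanging off junctions, floating islands of
    recurrent error k-mers, and spurious connectors.  True paths (long, or
    near the reference coverage) are untouched."""
    unitigs = _build_unitigs(counts, k)
    drop: set[str] = set()
    for seq, cov, _start, _end in unitigs:
        if len(seq) < 2 * k and cov < max(2.5, 0.25 * ref_cov):
            drop.update(_unitig_kmers(seq, k))
    if not drop:
        return counts
    return {km: c for km, c in counts.items() if km not in drop}


def _merge_bubbles(
    counts: dict[str, int], k: int, max_divergence: float
) -> dict[str, int]:
    """Collapse parallel unitigs between the same two nodes when their
    divergence is within ``max_divergence`` (keep the higher-coverage path);
    more diverged bubbles -- distinct mutant types -- are preserved."""
    unitigs = _build_unitigs(counts, k)
    groups: dict[tuple[str, str], list[tuple[str, float]]] = defaultdict(list)
    for seq, cov, start, end in unitigs:
        groups[(start, end)].append((seq, cov))
    drop: set[str] = set()
    for (start, end), members in groups.items():
        if len(members) < 2 or start == end:
            continue
        members.sort(key=lambda m: -m[1])
        keep_seq = members[0][0]
        for seq, _cov in members[1:]:
            if divergence(seq, keep_seq) <= max_divergence:
                drop.update(set(_unitig_kmers(seq, k)) - set(_unitig_kmers(keep_seq, k)))
    if not drop:
        return counts
    return {km: c for km, c in counts.items() if km not in drop}


def assemble(
    reads,
    k: int = DEFAULT_K,
    min_contig: int = DEFAULT_MIN_CONTIG,
    max_divergence: float = DEFAULT_MAX_DIVERGENCE,
    coverage_cutoff: int | str = "auto",
    backend: str = "builtin",
) -> ContigSet:
    """Assemble reads (strings or ReadPairs) into contigs.

    Raises :class:`AssemblyFailure` if no contig of at least ``min_contig``
    bases survives.
    """
    if backend == "external":
        return velvet_assemble(reads, k=k, min_contig=min_contig,
                               max_divergence=max_divergence)
    if backend != "builtin":
        raise ParameterError(f"unknown assembly backend: {backend!r}")
    seqs = _read_sequences(reads)
    if not seqs:
        raise AssemblyFailure("no reads to assemble")
    if k < 3 or k >= min(len(s) for s in seqs):
        raise ParameterError("k must satisfy 3 <= k < read length")

    counts = _count_kmers(seqs, k)
    cutoff = _auto_cutoff(counts) if coverage_cutoff == "auto" else int(coverage_cutoff)
    counts = {km: c for km, c in counts.items() if c >= cutoff}
    if counts:
        ref_cov = float(_weighted_median_count(counts))
        # iterate graph cleaning to a fixed point: purging an error tip can
        # expose a mergeable bubble and vice versa
        for _ in range(5):
            before = len(counts)
            counts = _purge_low_coverage(counts, k, ref_cov)
            counts = _merge_bubbles(counts, k, max_divergence)
            if len(counts) == before:
                break
    unitigs = _build_unitigs(counts, k) if counts else []
    contigs = [
        Contig(id=f"contig_{i}", sequence=seq, coverage=cov)
        for i, (seq, cov, _s, _e) in enumerate(
            sorted(unitigs, key=lambda u: -len(u[0]))
        )
        if len(seq) >= min_contig
    ]
    if not contigs:
        raise AssemblyFailure(
            f"no contig of length >= {min_contig} assembled "
            f"({len(unitigs)} unitigs, k-mer cutoff {cutoff})"
        )
    return ContigSet(contigs=contigs, backend="builtin")


def orient_contigs(
    contig_set: ContigSet,
    min_identity: float = DEFAULT_MIN_ORIENT_IDENTITY,
) -> OrientedSet:
    """Express every contig on the strand of the longest contig.

    Each contig is aligned to the longest in both orientations; the better
    one is kept if its per-base identity clears ``min_identity``, otherwise
    the experiment fails with :class:`StrandednessFailure` (the failure mode
    that dominates unsuccessful reconstructions).
    """
    if len(contig_set) == 0:
        raise ParameterError("no contigs to orient")
    ref = contig_set.longest()
    out = [OrientedContig(ref.id, ref.sequence, flipped=False, identity=1.0)]
    for c in contig_set.contigs:
        if c is ref:
            continue
        fwd = align_infix(c.sequence, ref.sequence)
        rc_seq = revcomp(c.sequence)
        rev = align_infix(rc_seq, ref.sequence)
        if fwd.identity >= rev.identity:
            best, seq, flipped = fwd, c.sequence, False
        else:
            best, seq, flipped = rev, rc_seq, True
        if best.identity < min_identity:
            raise StrandednessFailure(
                f"contig {c.id}: best orientation identity "
                f"{best.identity:.3f} < {min_identity}"
            )
        out.append(OrientedContig(c.id, seq, flipped, best.identity))
    return OrientedSet(contigs=out)


@dataclass
class ConsensusAlignment:
    """Gapped multiple alignment: '-' is an internal gap (votes as gap),
    '.' marks columns outside a contig's aligned span (no vote)."""

    rows: list[str]
    ids: list[str]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "").replace(".", "")

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n{row}\n")


def msa(oriented: OrientedSet, backend: str = "builtin") -> ConsensusAlignment:
    """Multiple-align oriented contigs.

    The builtin backend is a center-star progressive alignment seeded on the
    longest contig: every contig is aligned to the center, and insertions
    relative to the center open shared gap columns ("once a gap, always a
    gap").
    """
    if backend == "external":
        return muscle_msa(oriented)
    if backend != "builtin":
        raise ParameterError(f"unknown msa backend: {backend!r}")
    if len(oriented) == 0:
        raise ParameterError("no contigs to align")
    center = oriented.contigs[0].sequence
    Lc = len(center)
    per_row: list[tuple[dict[int, str], dict[int, str], int, int]] = []
    ins_len = defaultdict(int)  # center position -> max insertion before it

    for oc in oriented.contigs[1:]:
        aln = align_infix(oc.sequence, center)
        aligned: dict[int, str] = {}
        inserts: dict[int, str] = {}
        tpos = aln.target_start
        qpos = 0
        q = oc.sequence
        for n, op in aln.cigar:
            if op in ("=", "X", "M"):
                for _ in range(n):
                    aligned[tpos] = q[qpos]
                    tpos += 1
                    qpos += 1
            elif op == "D":  # gap in query against center
                for _ in range(n):
                    aligned[tpos] = "-"
                    tpos += 1
            elif op == "I":  # bases of the query absent from center
                inserts[tpos] = inserts.get(tpos, "") + q[qpos : qpos + n]
                qpos += n
        per_row.append((aligned, inserts, aln.target_start, tpos))
        for t, s in inserts.items():
            ins_len[t] = max(ins_len[t], len(s))

    def render(aligned, inserts, start, end, is_center=False):
        parts: list[str] = []
        for t in range(Lc + 1):
            gap = ins_len.get(t, 0)
            if gap:
                s = inserts.get(t, "") if not is_center else ""
                pad = "-" if (not is_center and start <= t <= end) else ("-" if is_center else ".")
                parts.append(s + pad * (gap - len(s)))
            if t < Lc:
                if is_center:
                    parts.append(center[t])
                elif start <= t < end:
                    parts.append(aligned.get(t, "."))
                else:
                    parts.append(".")
        return "".join(parts)

    rows = [render({}, {}, 0, Lc, is_center=True)]
    for aligned, inserts, start, end in per_row:
        rows.append(render(aligned, inserts, start, end))
    ids = [oc.id for oc in oriented.contigs]
    return ConsensusAlignment(rows=rows, ids=ids)


def majority_consensus(alignment: ConsensusAlignment) -> str:
    """Per-column majority vote over {A, C, G, T, gap}.

    Columns won by the gap symbol are removed; no-vote symbols ('.') are
    ignored; ties break deterministically in the fixed order
    A < C < G < T < '-'.
    """
    if not alignment.rows:
        raise ParameterError("empty alignment")
    order = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
    out: list[str] = []
    for col in zip(*alignment.rows):
        counts: dict[str, int] = {}
        for sym in col:
            if sym in order:
                counts[sym] = counts.get(sym, 0) + 1
        if not counts:
            continue
        winner = min(counts, key=lambda s: (-counts[s], order[s]))
        if winner != "-":
            out.append(winner)
    return "".join(out)


def reconstruct_consensus(
    reads,
    k: int = DEFAULT_K,
    min_contig: int = DEFAULT_MIN_CONTIG,
    max_divergence: float = DEFAULT_MAX_DIVERGENCE,
    min_identity: float = DEFAULT_MIN_ORIENT_IDENTITY,
    backend: str = "builtin",
) -> tuple[str, ContigSet]:
    """Assemble, orient, align and vote; returns (consensus, contigs)."""
    contigs = assemble(reads, k=k, min_contig=min_contig,
                       max_divergence=max_divergence, backend=backend)
    oriented = orient_contigs(contigs, min_identity=min_identity)
    alignment = msa(oriented, backend=backend)
    return majority_consensus(alignment), contigs


# --------------------------------------------------------------------------
# external-tool adapters (used only when the binaries are installed)

def velvet_assemble(
    reads,
    k: int = DEFAULT_K,
    min_contig: int = DEFAULT_MIN_CONTIG,
    max_divergence: float = DEFAULT_MAX_DIVERGENCE,
) -> ContigSet:
    """Adapter around Velvet (velveth/velvetg) with the canonical flags
    (-exp_cov auto, -min_contig_lgth, -max_divergence)."""
    if shutil.which("velveth") is None or shutil.which("velvetg") is None:
        raise ParameterError("velvet binaries not found on PATH")
    seqs = _read_sequences(reads)
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "reads.fa"
        with open(fasta, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f">r{i}\n{s}\n")
        subprocess.run(
            ["velveth", tmp, str(k), "-short", "-fasta", str(fasta)],
            check=True, capture_output=True,
        )
        subprocess.run(
            ["velvetg", tmp, "-exp_cov", "auto",
             "-min_contig_lgth", str(min_contig),
             "-max_divergence", str(max_divergence)],
            check=True, capture_output=True,
        )
        contigs = []
        name, chunks = None, []
        with open(Path(tmp) / "contigs.fa") as fh:
            for line in fh:
                if line.startswith(">"):
                    if name and chunks:
                        contigs.append(Contig(name, "".join(chunks)))
                    name, chunks = line[1:].split()[0], []
                else:
                    chunks.append(line.strip())
            if name and chunks:
                contigs.append(Contig(name, "".join(chunks)))
    if not contigs:
        raise AssemblyFailure("velvet produced no contigs")
    return ContigSet(contigs=contigs, backend="external")


def muscle_msa(oriented: OrientedSet) -> ConsensusAlignment:
    """Adapter around muscle (-maxiters 1 -diags)."""
    if shutil.which("muscle") is None:
        raise ParameterError("muscle binary not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        inp, outp = Path(tmp) / "in.fa", Path(tmp) / "out.fa"
        with open(inp, "w") as fh:
            for oc in oriented.contigs:
                fh.write(f">{oc.id}\n{oc.sequence}\n")
        subprocess.run(
            ["muscle", "-in", str(inp), "-out", str(outp),
             "-maxiters", "1", "-diags"],
            check=True, capture_output=True,
        )
        rows, ids = [], []
        name, chunks = None, []
        with open(outp) as fh:
            for line in fh:
                if line.startswith(">"):
                    if name is not None:
                        ids.append(name)
                        rows.append("".join(chunks))
                    name, chunks = line[1:].strip(), []
                else:
                    chunks.append(line.strip())
            if name is not None:
                ids.append(name)
                rows.append("".join(chunks))
    return ConsensusAlignment(rows=rows, ids=ids)
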