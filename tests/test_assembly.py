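"""Builtin assembler, contig orientation, center-star MSA and majority
consensus."""

import numpy as np
import pytest

from ngsam import (
    AssemblyFailure,
    ConsensusAlignment,
    Contig,
    ContigSet,
    ErrorModel,
    MutantPool,
    MutationSpectrum,
    StrandednessFailure,
    assemble,
    build_unrest,
    majority_consensus,
    msa,
    orient_contigs,
    revcomp,
    simulate_branch_mutations,
    simulate_reads,
)
from ngsam._align import align_infix
from ngsam._seq import random_dna


def _pool(seqs):
    return MutantPool(
        sequences=list(seqs),
        founders=list(range(len(seqs))),
        multiplicities=[1] * len(seqs),
        weights=[1] * len(seqs),
    )


def _mutant(template, rng, beta=0.012, replications=9):
    """~10% mutated copy of the template."""
    model = build_unrest(MutationSpectrum.default()).with_beta(beta)
    return simulate_branch_mutations(template, replications, model, rng)


class TestAssemble:
    def test_single_mutant_reconstructed_nearly_full_length(self, rng):
        source = random_dna(1000, rng)
        reads = simulate_reads(_pool([source]), rng, total_coverage=200.0,
                               error_model=ErrorModel.perfect())
        contigs = assemble(reads)
        best = contigs.longest()
        aln = align_infix(best.sequence, source) \
            if len(best.sequence) <= len(source) else align_infix(source, best.sequence)
        assert aln.matches >= 0.95 * 1000

    def test_two_diverged_mutants_stay_separate(self, rng):
        template = random_dna(1200, rng)
        a, b = _mutant(template, rng), _mutant(template, rng)
        reads = simulate_reads(_pool([a, b]), rng, total_coverage=400.0,
                               error_model=ErrorModel.perfect())
        contigs = assemble(reads)
        # provenance oracle: classify each contig by alignment distance
        hits_a = hits_b = 0
        for c in contigs.contigs:
            seqs = (c.sequence, revcomp(c.sequence))
            da = min(align_infix(s, a).distance for s in seqs)
            db = min(align_infix(s, b).distance for s in seqs)
            if da < db:
                hits_a += 1
            elif db < da:
                hits_b += 1
        assert hits_a >= 1 and hits_b >= 1

    def test_empty_read_set_fails(self):
        with pytest.raises(AssemblyFailure):
            assemble([])

    def test_min_contig_filter(self, rng):
        source = random_dna(1000, rng)
        reads = simulate_reads(_pool([source]), rng, total_coverage=200.0,
                               error_model=ErrorModel.perfect())
        contigs = assemble(reads, min_contig=400)
        assert all(len(c) >= 400 for c in contigs.contigs)


class TestOrientation:
    def test_single_contig_keeps_identity(self):
        cs = ContigSet([Contig("c0", "ACGTAGGCTA" * 50)])
        oriented = orient_contigs(cs)
        assert not oriented.contigs[0].flipped

    def test_reverse_complement_contig_is_flipped(self, rng):
        seq = random_dna(800, rng)
        cs = ContigSet([Contig("c0", seq), Contig("c1", revcomp(seq[100:600]))])
        oriented = orient_contigs(cs)
        assert oriented.contigs[1].flipped
        assert oriented.contigs[1].sequence == seq[100:600]

    def test_unrelated_contig_fails_strandedness(self, rng):
        cs = ContigSet([
            Contig("c0", random_dna(1000, rng)),
            Contig("c1", random_dna(500, rng)),
        ])
        with pytest.raises(StrandednessFailure):
            orient_contigs(cs)

    def test_orientation_invariance_of_consensus(self, rng):
        # flipping any non-reference contig must not change the consensus
        # (the longest contig fixes the reference strand; flipping *it*
        # changes tied columns because the deterministic A<C<G<T tie-break
        # is not strand-symmetric)
        template = random_dna(900, rng)
        mutants = [template + "ACGTAC"] + [_mutant(template, rng) for _ in range(4)]
        cs1 = ContigSet([Contig(f"c{i}", s) for i, s in enumerate(mutants)])
        flip = [s if i % 2 == 0 else revcomp(s) for i, s in enumerate(mutants)]
        flip[0] = mutants[0]  # keep the longest on its original strand
        cs2 = ContigSet([Contig(f"c{i}", s) for i, s in enumerate(flip)])
        cons1 = majority_consensus(msa(orient_contigs(cs1)))
        cons2 = majority_consensus(msa(orient_contigs(cs2)))
        assert cons1 == cons2


class TestMsa:
    def test_identical_contigs_align_without_gaps(self, rng):
        seq = random_dna(600, rng)
        cs = ContigSet([Contig(f"c{i}", seq) for i in range(3)])
        aln = msa(orient_contigs(cs))
        assert all("-" not in row for row in aln.rows)
        assert all(aln.degapped(i) == seq for i in range(3))

    def test_single_contig_single_row(self, rng):
        seq = random_dna(500, rng)
        aln = msa(orient_contigs(ContigSet([Contig("c0", seq)])))
        assert aln.rows == [seq]

    def test_single_substitution_gives_one_mismatch_column(self, rng):
        seq = random_dna(600, rng)
        other = seq[:300] + ("A" if seq[300] != "A" else "C") + seq[301:]
        aln = msa(orient_contigs(ContigSet([Contig("c0", seq), Contig("c1", other)])))
        assert all("-" not in row for row in aln.rows)
        mismatches = sum(a != b for a, b in zip(*aln.rows))
        assert mismatches == 1

    def test_rows_degap_to_input_contigs(self, rng):
        template = random_dna(700, rng)
        mutants = [_mutant(template, rng) for _ in range(4)]
        oriented = orient_contigs(
            ContigSet([Contig(f"c{i}", s) for i, s in enumerate(mutants)])
        )
        aln = msa(oriented)
        for i, oc in enumerate(oriented.contigs):
            assert aln.degapped(i) == oc.sequence


class TestMajorityConsensus:
    def test_column_majority(self):
        aln = ConsensusAlignment(rows=["ACGT", "ACGT", "ACTT"], ids=list("abc"))
        assert majority_consensus(aln) == "ACGT"

    def test_single_row_degaps(self):
        aln = ConsensusAlignment(rows=["AC-GT"], ids=["a"])
        assert majority_consensus(aln) == "ACGT"

    def test_idempotent_on_identical_rows(self):
        aln = ConsensusAlignment(rows=["ACGT"] * 5, ids=list("abcde"))
        assert majority_consensus(aln) == "ACGT"

    def test_gap_majority_columns_are_removed(self):
        aln = ConsensusAlignment(rows=["A-GT", "A-GT", "ACGT"], ids=list("abc"))
        assert majority_consensus(aln) == "AGT"

    def test_no_vote_symbols_are_ignored(self):
        # '.' marks columns outside a contig's span: a single covering row
        # decides those columns
        aln = ConsensusAlignment(rows=["ACGT", "..GT", "..GT"], ids=list("abc"))
        assert majority_consensus(aln) == "ACGT"

    def test_majority_wins_when_over_half_rows_agree(self, rng):
        x = random_dna(200, rng)
        y = _mutant(x, rng)
        aln = ConsensusAlignment(rows=[x, x, x, y, y], ids=list("abcde"))
        assert majority_consensus(aln) == x
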