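"""UNREST model construction, branch mutation sampling, calibration and
identity-by-descent of mutations on genealogies."""

import numpy as np
import pytest

from ngsam import (
    CalibrationError,
    Genealogy,
    MutationSpectrum,
    ParameterError,
    PCRParams,
    build_unrest,
    calibrate_scaling,
    mutate_pool,
    sample_genealogy,
    simulate_branch_mutations,
    simulate_counts,
)
from ngsam._seq import BASES
from ngsam.mutagenesis import expected_mutated_fraction

UNIFORM = MutationSpectrum({a + b: 1.0 for a in BASES for b in BASES if a != b})


class TestBuildUnrest:
    def test_uniform_spectrum_gives_equal_rates_and_zero_row_sums(self):
        m = build_unrest(UNIFORM)
        off = m.Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, off[0])
        assert np.allclose(m.Q.sum(axis=1), 0)

    def test_single_pair_spectrum_is_degenerate(self):
        m = build_unrest(MutationSpectrum({"AG": 2.0}))
        off = m.Q.copy()
        np.fill_diagonal(off, 0)
        assert np.count_nonzero(off) == 1
        assert off[BASES.index("A"), BASES.index("G")] > 0

    def test_all_zero_spectrum_rejected(self):
        with pytest.raises(ParameterError):
            MutationSpectrum({"AG": 0.0})

    def test_default_spectrum_is_transition_biased(self):
        m = build_unrest(MutationSpectrum.default())
        i = {b: k for k, b in enumerate(BASES)}
        transitions = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
        ts = sum(m.Q[i[a], i[b]] for a, b in transitions)
        tv = -np.trace(m.Q) - ts
        assert ts > tv


class TestBranchMutations:
    def test_zero_replications_is_identity(self, unrest_model, rng):
        seq = "ACGT" * 100
        assert simulate_branch_mutations(seq, 0, unrest_model, rng) == seq

    def test_zero_beta_is_identity(self, unrest_model, rng):
        seq = "ACGT" * 100
        m = unrest_model.with_beta(0.0)
        assert simulate_branch_mutations(seq, 7, m, rng) == seq

    def test_uniform_spectrum_matches_jukes_cantor_closed_form(self, rng):
        # with all 12 weights equal the process is Jukes-Cantor with total
        # rate 1, so P(site unchanged after time t) = 1/4 + 3/4 exp(-4t/3)
        beta, t = 0.03, 1
        m = build_unrest(UNIFORM).with_beta(beta)
        seq = "A" * 100_000
        out = simulate_branch_mutations(seq, t, m, rng)
        p_change = 3 / 4 * (1 - np.exp(-4 * beta * t / 3))
        observed = sum(a != b for a, b in zip(seq, out)) / len(seq)
        se = np.sqrt(p_change * (1 - p_change) / len(seq))
        assert abs(observed - p_change) < 4 * se

    def test_substitution_counts_recover_spectrum_ratios(self, rng):
        spectrum = MutationSpectrum({"AG": 0.5, "CT": 0.25, "GA": 0.25})
        m = build_unrest(spectrum).with_beta(0.02)
        seq = ("ACGT" * 50_000)
        out = simulate_branch_mutations(seq, 1, m, rng)
        counts = {}
        for a, b in zip(seq, out):
            if a != b:
                counts[a + b] = counts.get(a + b, 0) + 1
        total = sum(counts.values())
        # at small branch length multiple hits are negligible, so observed
        # ordered substitution proportions track the spectrum weights
        for pair, weight in spectrum.weights.items():
            obs = counts.get(pair, 0) / total
            se = np.sqrt(weight * (1 - weight) / total)
            assert abs(obs - weight) < 4 * max(se, 1e-3), pair

    def test_negative_replications_rejected(self, unrest_model, rng):
        with pytest.raises(ParameterError):
            simulate_branch_mutations("ACGT", -1, unrest_model, rng)


class TestCalibration:
    def test_calibrated_model_reproduces_target_fraction(self, calibrated_model):
        # independent re-simulation: full stochastic mutagenesis of sampled
        # molecules from fresh 10-cycle PCRs
        rng = np.random.default_rng(31)
        template = "ACGT" * 250
        params = PCRParams(1000, 0.75, 10)
        fractions = []
        for _ in range(40):
            traj = simulate_counts(params, rng)
            gen = sample_genealogy(params, 10, traj, rng)
            pool = mutate_pool(gen, template, calibrated_model, rng)
            for s in pool.sequences:
                fractions.append(
                    sum(a != b for a, b in zip(s, template)) / len(template)
                )
        mean = np.mean(fractions)
        se = np.std(fractions) / np.sqrt(len(fractions))
        assert abs(mean - 0.05) < max(2 * se, 0.005)

    def test_tiny_target_fraction_gives_tiny_beta(self, unrest_model):
        m = calibrate_scaling(
            unrest_model, target_fraction=1e-4, n_cycles=10,
            n_genealogies=3, sample_size=20, rng=np.random.default_rng(0),
        )
        assert 0 < m.beta < 1e-4

    def test_non_bracketing_bounds_raise(self, unrest_model):
        with pytest.raises(CalibrationError):
            calibrate_scaling(
                unrest_model, target_fraction=0.5, beta_bounds=(1e-9, 1e-8),
                n_genealogies=2, sample_size=10, rng=np.random.default_rng(0),
            )

    def test_expected_fraction_monotone_in_beta(self, unrest_model):
        depths = np.array([3, 4, 5])
        f = [
            expected_mutated_fraction(unrest_model.with_beta(b), depths)
            for b in (0.001, 0.01, 0.1)
        ]
        assert f[0] < f[1] < f[2]


class TestMutatePool:
    def test_zero_beta_pool_is_all_template(self, unrest_model, rng):
        params = PCRParams(5, 0.75, 6)
        traj = simulate_counts(params, rng)
        gen = sample_genealogy(params, 5, traj, rng)
        pool = mutate_pool(gen, "ACGT" * 25, unrest_model.with_beta(0.0), rng)
        assert all(s == "ACGT" * 25 for s in pool.sequences)

    def test_star_genealogy_gives_template_copies(self, unrest_model, rng):
        params = PCRParams(10, 0.0, 4)
        traj = simulate_counts(params, rng)
        gen = sample_genealogy(params, 6, traj, rng)  # all branch lengths 0
        pool = mutate_pool(gen, "ACGTACGT", unrest_model.with_beta(0.5), rng)
        assert all(s == "ACGTACGT" for s in pool.sequences)

    def test_shared_branch_mutations_are_identical_by_descent(self, rng):
        # hand-built tree: root -> internal (5 replications) -> two leaves
        # at distance 0, so leaves share exactly the internal branch
        gen = Genealogy(
            children=[[], [], [(0, 0), (1, 0)]], n_leaves=2, roots=[(2, 0)]
        )
        m = build_unrest(MutationSpectrum.default()).with_beta(0.05)
        gen.children[2] = [(0, 0), (1, 0)]
        gen2 = Genealogy(
            children=[[], [], [(0, 0), (1, 0)], [(2, 5)]],
            n_leaves=2,
            roots=[(3, 0)],
        )
        template = "ACGT" * 500
        pool = mutate_pool(gen2, template, m, rng)
        assert pool.sequences[0] == pool.sequences[1]
        assert pool.sequences[0] != template  # mutations did occur w.h.p.

    def test_distinct_branches_mutate_independently(self, rng):
        gen = Genealogy(
            children=[[], [], [(0, 8), (1, 8)]], n_leaves=2, roots=[(2, 0)]
        )
        m = build_unrest(MutationSpectrum.default()).with_beta(0.05)
        pool = mutate_pool(gen, "ACGT" * 500, m, rng)
        assert pool.sequences[0] != pool.sequences[1]
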