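# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, the numerical decisions, and what the simulation
does and does not capture about real experiments.

## PCR as a branching process, genealogies by backward simulation

Every PCR is a discrete-cycle branching process: a molecule present at the
start of a cycle is duplicated with probability λ (the per-cycle
efficiency), so counts evolve as `N_i = N_{i-1} + Binomial(N_{i-1}, λ)` and
the expectation after n cycles is `S·(1+λ)^n`. λ defaults to 0.75,
a typical empirical estimate for efficient PCR; it is stored per cycle, so
cycle-dependent efficiencies can be supplied.

Forward simulation of every replication is infeasible at realistic counts
(the first PCR alone produces ~3.6×10⁸ molecules), and unnecessary: only
the sampled molecules' ancestry matters. `sample_genealogy` therefore walks
the cycles backward, conditional on the realized count trajectory. At cycle
i, each sampled lineage is one of the `N_i − N_{i-1}` fresh product
molecules with hypergeometric probability; products pick *distinct*
templates uniformly among the cycle-(i−1) pool (a molecule is duplicated at
most once per cycle), a product landing on a molecule that already carries
a lineage coalesces with it, and each product step adds one replication
event to the branch. Lineages surviving to cycle 0 map to distinct
founders. Populations above 10⁸ use the binomial limit of the
hypergeometric draw; the without-replacement correction is O(k²/N) there.
The sampler is validated in distribution against a brute-force forward
simulation that tracks every parent link (tests).

## Substitution model and calibration

Error-prone PCR with base analogues produces an asymmetric substitution
spectrum, encoded here as 12 relative weights and turned into a general
non-reversible (UNREST) rate matrix: off-diagonal rates proportional to the
weights, diagonals closing the rows, no reversibility constraint. Q is
normalized to one expected substitution per site per time unit at uniform
composition, so the branch scaling β reads directly as substitutions per
site per replication event. Branch "time" is the integer replication count:
mutations arise at replications, not in calendar time. Substitutions only —
the analogue chemistry does not produce indels at appreciable rates, and
the UNREST family is substitution-only.

The exact published spectrum for the analogue mixture is not reproduced
here; the shipped default is an explicitly approximate, transition-biased
spectrum (A→G/T→C dominant, weaker G→A/C→T, minor transversions) and any
measured 12-weight spectrum can be supplied as configuration. Since β is
calibrated to a target mutation *load*, the spectrum shape affects which
substitutions occur but not how many.

Calibration (`calibrate_scaling`) targets the benchmark load of the
mutagenic chemistry: 5% of sites mutated per molecule sampled after a
10-cycle mutagenic PCR. A set of genealogies is pre-simulated once
(default: 20 genealogies of 100 molecules at S0 = 5000, λ = 0.75); given
the sampled replication depths, the expected mutated fraction is exact in
the site dimension (via `exp(t·β·Q)` diagonals at uniform composition) and
monotone in β, so log-scale bisection converges cleanly. The calibration
assumes the cleanup PCR is mutation-free, which is also how the protocol
stage treats it. Applying the calibrated β to the 20 cycles used in the
experiments yields ≈10% mutated sites (slightly under 2× 5% because of
multiple hits). Independent stochastic re-simulations confirm both numbers
(tests, acceptance script).

## Protocol orchestration

Stage counts follow the chain S0 → S1 (mutagenic PCR) → S2 (dilution d1) →
S3 (cleanup PCR) → S4 (dilution d2) → S5 (final PCR). Dilution sampling is
Poisson with mean `count/factor`; a factor of exactly 1 means the step is
not performed and the count is carried over unchanged (taking the whole
solution is deterministic). Zero molecules after either dilution is an
experiment failure (`empty_sample`). Reference defaults: S0 = 5000,
n1 = n2 = 20, n3 = 30, d1 = 7×10⁴, d2 = 1.6×10⁷, chosen (via the
deterministic expectation chain `expected_stage_counts`) to leave ≈23
molecules at the second dilution.

Only the S4 molecules' lineages matter for sequence diversity. The cleanup
PCR genealogy is sampled backward for the S4 molecules to find their
distinct S2 ancestors — two S4 molecules sharing an S2 ancestor are one
mutant type, with identical sequences by construction — and the mutagenic
genealogy is then sampled only for those ancestors and mutated branch by
branch. `genealogy_sample_cap` (default 200, comfortably above typical S4
values at the reference dilutions) bounds this sample; exceeding it raises
a configuration error rather than silently truncating, and the grid runners
record such runs as `config_cap` failures. Each S4 molecule is amplified
through the final PCR as an independent single-founder branching process;
the per-type descendant totals become sequencing-coverage weights.

## Read simulation

Fragment lengths are log-normal with natural-scale arithmetic mean 400 bp
and coefficient of variation 0.055 (the CV is taken on the natural scale;
the underlying normal parameters are σ² = ln(1+CV²),
μ = ln(mean) − σ²/2). With 101-bp read pairs this implies a mean
unsequenced insert of 198 bp. Fragments shorter than the read length are
redrawn (no adapter read-through), as are fragments longer than the
molecule. Total coverage (default 4,000×, ≈200× per mutant type at the
reference dilutions) fixes the number of pairs; pairs are split across
mutants proportionally to final-PCR weights with largest-remainder
rounding.

Errors are substitutions drawn from a position-ramped model (default
0.001 at the 5' end to 0.01 at the 3' end, the familiar quality decay of
short-read instruments); emitted qualities are the Phred encoding of the
per-position model rate. This simple model preserves the error *load* that
stresses assembly; it does not reproduce instrument-specific intensity
artefacts, indel errors, optical duplicates or lane effects.

Fragment geometry imposes a minimum practical target size: fragment start
positions are uniform over the molecule, so a target not much longer than
the mean fragment length leaves a mid-molecule stretch that only the
unsequenced inserts cross (e.g. on a 500-bp molecule, ~400-bp fragments
start within the first ~100 bp and positions ~200–300 receive no reads at
all). Such targets fail at the assembly stage — in the simulation exactly
as they would on a real instrument with that library.

## Assembly and consensus

The builtin assembler is a deliberately small de Bruijn implementation.
K-mers (k = 90 against 101-bp reads: specificity over coverage) are counted
for each read *and its reverse complement*, so both strand paths of every
mutant receive full coverage and each mutant assembles on both strands;
the orientation step folds the duplicates onto one strand. Cleaning
proceeds from a coverage estimate — the count-weighted median k-mer
multiplicity, which sits at the typical *true* k-mer coverage because
error k-mers are numerous but carry little mass:

* k-mers below `max(2, 10%·coverage)` are dropped;
* short (< 2k) unitigs far below coverage (< max(2.5, 25%)) are purged —
  error tips, floating islands of recurrent error k-mers, spurious
  connectors;
* parallel unitigs between the same two nodes are merged onto the
  higher-coverage path only when their divergence is ≤ `max_divergence`
  (default 0.1) — residual error bubbles collapse while mutant types,
  which diverge by roughly twice the per-molecule mutation load (~18%),
  are preserved as separate contigs;
* purge and merge iterate to a fixed point (≤ 5 rounds), then contigs
  shorter than `min_contig` (400) are dropped; none surviving is an
  assembly failure.

Orientation aligns every contig to the longest one in both orientations
(edlib infix alignment) and keeps the better if its per-base identity
clears 0.70. The threshold sits in a wide empirical gap: correctly oriented
contigs of sibling mutants score ≈0.82+, wrong orientations and unrelated
sequence ≈0.56–0.62 (an affine-score threshold was considered and
rejected: optimal edit-distance alignments of *random* sequences still
collect large positive affine-style scores, so a fixed small-score cutoff
does not reject them). A contig failing both orientations aborts the
experiment as a strandedness failure — the dominant failure mode — rather
than being dropped.

The MSA is a center-star progressive alignment seeded on the longest
contig: each contig is aligned to the center, insertions relative to the
center open shared gap columns. The consensus takes the per-column majority
over {A, C, G, T, gap}; gap-majority columns are removed; ties break in the
fixed order A < C < G < T < gap, trading hidden randomness for determinism
(one consequence: voting is not strand-symmetric in tied columns, so the
consensus is invariant to flipping any non-reference contig but can differ
in tied columns if the *reference* strand flips). Columns outside a
contig's aligned span do not vote at all — a partial contig abstains where
it has no data instead of voting gaps that would delete covered target
columns.

## Evaluation

The consensus is aligned to the target in both orientations; the best must
beat the runner-up by a factor 1.1 in matched bases (configurable,
logged), otherwise the run fails as ambiguous. Percent identity is
matches per alignment column over the aligned portion; percent length is
the aligned target span over the target length; percent correct is their
product. Tracking mutations (one substitution per repeat unit in tandem
targets) are never seen by the assembler; they only report whether each
unit was recovered in place. Per-experiment randomness derives from a
master seed through `numpy.random.SeedSequence` spawn keys (stage index ×
experiment index), so any grid rerun is byte-identical.

## Problem sizes

The full study grids (unit lengths 4–4,000 × unit counts 4–100 under a
30-kb cap with five replicates each, and the dilution sweep on an 11.4-kb
tandem target) are available through `grid_specs` / `run_setting1` /
`run_setting2` and the CLI. The shipped tests and the acceptance script
exercise the same machinery at reduced sizes chosen to keep the suite
quick while preserving every qualitative regime: a 4 × 500-bp target for
end-to-end reconstruction (well inside the safe region, ≈23 mutant types
at ≈174× each), a 3×3 dilution mini-grid spanning the assembly-failure and
empty-sample corners on a 2 × 500-bp target, 500–600 replicates for count
distributions and 500 sampled molecules for mutation loads.

## Known limitations

* The mutation spectrum default is an approximation; quantitative
  spectrum-dependent conclusions require a measured spectrum.
* No plateau-phase PCR kinetics, primer exhaustion or chimera formation;
  efficiency is constant across cycles by default.
* The read simulator has no indel errors or instrument intensity model;
  the builtin assembler ignores pairing information and its
  coverage-estimation heuristics differ from Velvet's `-exp_cov auto`.
* Consensus calling is plain majority vote; probabilistic consensus
  methods that model alignment uncertainty would be strictly stronger.
* The simulated success rates say nothing about wet-lab factors outside
  the model: long-fragment PCR feasibility, contamination risk in
  few-molecule PCR, analogue carry-over chemistry.
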