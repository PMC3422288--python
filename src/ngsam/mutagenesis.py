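"""Error-prone PCR mutagenesis: the UNREST substitution model, its
calibration, and placing mutations on PCR genealogies.

Mutagenic PCR with nucleotide analogues (dPTP, 8-oxo-dGTP) produces a
characteristic, asymmetric spectrum of base substitutions.  That spectrum is
encoded as 12 relative weights (one per ordered pair X->Y) from which a
general non-reversible (UNREST) 4x4 rate matrix Q is built -- no symmetry or
reversibility constraint is imposed.  Branch "time" on a PCR genealogy is
the integer number of replication events, scaled by a factor ``beta``;
``beta`` is the one free parameter and is calibrated so that molecules
sampled from a simulated mutagenic PCR carry a prescribed mean fraction of
mutated sites (5% after 10 cycles is the benchmark reported for the
error-prone PCR kit chemistry).  The process is substitution-only; indels
are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from ._seq import BASES, decode, encode
from .errors import CalibrationError, ParameterError
from .pcr import Genealogy, PCRParams, sample_genealogy, simulate_counts

#: Shipped default spectrum: a synthetic, transition-biased approximation of
#: the spectrum produced by dPTP / 8-oxo-dGTP mutagenesis (dPTP chiefly
#: drives A->G / T->C transitions, with weaker G->A / C->T; 8-oxo-dGTP adds
#: A->C / T->G and G->T / C->A transversions).  Relative weights only; any
#: measured spectrum can be supplied instead.
DEFAULT_SPECTRUM: dict[str, float] = {
    "AG": 0.30, "TC": 0.30,
    "GA": 0.10, "CT": 0.10,
    "AC": 0.05, "TG": 0.05,
    "GT": 0.03, "CA": 0.03,
    "AT": 0.01, "TA": 0.01,
    "GC": 0.01, "CG": 0.01,
}

_PAIRS = [a + b for a in BASES for b in BASES if a != b]


@dataclass(frozen=True)
class MutationSpectrum:
    """Relative weights of the 12 ordered base substitutions X->Y."""

    weights: dict[str, float]

    def __post_init__(self):
        w = {p: float(self.weights.get(p, 0.0)) for p in _PAIRS}
        unknown = set(self.weights) - set(_PAIRS)
        if unknown:
            raise ParameterError(f"unknown substitution labels: {sorted(unknown)}")
        if any(v < 0 for v in w.values()):
            raise ParameterError("spectrum weights must be non-negative")
        if not any(v > 0 for v in w.values()):
            raise ParameterError("spectrum must have at least one positive weight")
        object.__setattr__(self, "weights", w)

    @classmethod
    def default(cls) -> "MutationSpectrum":
        return cls(dict(DEFAULT_SPECTRUM))

    def matrix(self) -> np.ndarray:
        """4x4 weight matrix (zero diagonal), rows/cols ordered A,C,G,T."""
        m = np.zeros((4, 4))
        for pair, w in self.weights.items():
            m[BASES.index(pair[0]), BASES.index(pair[1])] = w
        return m


@dataclass(frozen=True)
class SubstitutionModel:
    """UNREST rate matrix plus the per-replication branch scaling ``beta``.

    Q is normalized so that one time unit produces on average one
    substitution per site under a uniform base composition; the calibrated
    ``beta`` therefore directly reads as the expected number of
    substitutions per site per replication event (before multiple hits).
    """

    Q: np.ndarray
    beta: float = 1.0

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        if Q.shape != (4, 4):
            raise ParameterError("Q must be 4x4")
        off = Q - np.diag(np.diag(Q))
        if (off < 0).any():
            raise ParameterError("off-diagonal rates must be non-negative")
        if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
            raise ParameterError("Q rows must sum to zero")
        if self.beta < 0:
            raise ParameterError("beta must be >= 0")
        object.__setattr__(self, "Q", Q)

    def with_beta(self, beta: float) -> "SubstitutionModel":
        return replace(self, beta=float(beta))

    def transition_matrix(self, replications: float) -> np.ndarray:
        """P(t) = expm(t * beta * Q) for t counted in replication events."""
        if replications == 0 or self.beta == 0:
            return np.eye(4)
        return expm(replications * self.beta * self.Q)

    def dump_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(BASES) + "\n")
            for i, b in enumerate(BASES):
                row = "\t".join(f"{self.Q[i, j]:.8g}" for j in range(4))
                fh.write(f"{b}\t{row}\n")


def build_unrest(spectrum: MutationSpectrum) -> SubstitutionModel:
    """Build the UNREST model with off-diagonal rates proportional to the
    spectrum weights, diagonals closing the rows, and beta = 1."""
    Q = spectrum.matrix()
    np.fill_diagonal(Q, 0.0)
    # mean substitution rate 1 per site per time unit at uniform composition
    Q /= Q.sum() / 4.0
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return SubstitutionModel(Q=Q, beta=1.0)


def simulate_branch_mutations(
    sequence: np.ndarray | str,
    replication_count: int,
    model: SubstitutionModel,
    rng: np.random.Generator,
) -> np.ndarray | str:
    """Evolve a sequence along a branch of ``replication_count`` replication
    events by exact per-site sampling from ``expm(t * beta * Q)``.

    Accepts either a DNA string or an integer-coded array (returned in
    kind).
    """
    if replication_count < 0:
        raise ParameterError("replication_count must be >= 0")
    as_str = isinstance(sequence, str)
    arr = encode(sequence) if as_str else np.asarray(sequence, dtype=np.uint8)
    if replication_count == 0 or model.beta == 0:
        out = arr.copy()
        return decode(out) if as_str else out
    P = model.transition_matrix(replication_count)
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    u = rng.random(arr.shape[0])
    out = (u[:, None] > cum[arr]).sum(axis=1).astype(np.uint8)
    return decode(out) if as_str else out


@dataclass
class MutantPool:
    """Distinct mutant molecules sampled by the second dilution.

    One entry per mutant type: its sequence, the cycle-0 founder of its
    mutagenic-PCR lineage, its multiplicity in the second-dilution sample,
    and its final-PCR descendant count (the weight that drives sequencing
    coverage).
    """

    sequences: list[str]
    founders: list[int]
    multiplicities: list[int]
    weights: list[int]

    def __post_init__(self):
        n = len(self.sequences)
        if not (len(self.founders) == len(self.multiplicities) == len(self.weights) == n):
            raise ParameterError("pool fields must be index-aligned")
        if n and len({len(s) for s in self.sequences}) != 1:
            raise ParameterError("pool sequences must share the template length")
        if any(m < 1 for m in self.multiplicities):
            raise ParameterError("multiplicities must be >= 1")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_molecules(self) -> int:
        return sum(self.multiplicities)


def mutate_pool(
    genealogy: Genealogy,
    template: str,
    model: SubstitutionModel,
    rng: np.random.Generator,
) -> MutantPool:
    """Place mutations on every branch of a genealogy and collect the leaf
    sequences.

    Mutations on shared ancestral branches are identical by descent in all
    descendant leaves.  Each leaf becomes one pool entry (multiplicity 1,
    weight 1); the protocol layer aggregates multiplicities and final-PCR
    weights.
    """
    tmpl = encode(template)
    leaf_seqs: dict[int, np.ndarray] = {}
    for root, _founder in genealogy.roots:
        stack = [(root, tmpl)]
        while stack:
            node, seq = stack.pop()
            if node < genealogy.n_leaves:
                leaf_seqs[node] = seq
            for child, blen in genealogy.children[node]:
                stack.append(
                    (child, simulate_branch_mutations(seq, blen, model, rng))
                )
    founders = genealogy.leaf_founders()
    return MutantPool(
        sequences=[decode(leaf_seqs[i]) for i in range(genealogy.n_leaves)],
        founders=[int(founders[i]) for i in range(genealogy.n_leaves)],
        multiplicities=[1] * genealogy.n_leaves,
        weights=[1] * genealogy.n_leaves,
    )


def expected_mutated_fraction(
    model: SubstitutionModel,
    depths: np.ndarray,
    composition: np.ndarray | None = None,
) -> float:
    """Mean fraction of sites differing from the template for molecules
    whose lineages carry the given replication counts (exact in the site
    dimension)."""
    if composition is None:
        composition = np.full(4, 0.25)
    frac = 0.0
    for d in np.asarray(depths):
        P = model.transition_matrix(int(d))
        frac += float(composition @ (1.0 - np.diag(P)))
    return frac / len(depths)


def calibrate_scaling(
    model: SubstitutionModel,
    target_fraction: float = 0.05,
    n_cycles: int = 10,
    efficiency: float = 0.75,
    n_start: int = 5000,
    sample_size: int = 100,
    n_genealogies: int = 20,
    tolerance: float = 1e-4,
    beta_bounds: tuple[float, float] = (1e-8, 1.0),
    rng: np.random.Generator | None = None,
) -> SubstitutionModel:
    """Calibrate ``beta`` so molecules sampled from a simulated
    ``n_cycles``-cycle mutagenic PCR carry ``target_fraction`` mutated sites
    on average.

    A set of genealogies is pre-simulated once (branching-process counts
    plus backward genealogy of ``sample_size`` molecules); the mean mutated
    fraction is then a deterministic, monotone function of ``beta`` --
    exact over sites given the sampled replication depths -- and is solved
    by bisection.  The calibration assumes the cleanup PCR introduces no
    mutations, so only the mutagenic cycles count.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ParameterError("target_fraction must lie in (0, 1)")
    if n_cycles < 1:
        raise ParameterError("n_cycles must be >= 1")
    if rng is None:
        rng = np.random.default_rng()

    params = PCRParams(n_start=n_start, efficiency=efficiency, n_cycles=n_cycles)
    depths = []
    for _ in range(n_genealogies):
        traj = simulate_counts(params, rng)
        gen = sample_genealogy(params, sample_size, traj, rng)
        depths.append(gen.leaf_depths())
    depths = np.concatenate(depths)

    def mean_fraction(beta: float) -> float:
        return expected_mutated_fraction(model.with_beta(beta), depths)

    lo, hi = beta_bounds
    f_lo, f_hi = mean_fraction(lo), mean_fraction(hi)
    if not f_lo <= target_fraction <= f_hi:
        raise CalibrationError(
            f"target fraction {target_fraction} not bracketed by beta bounds "
            f"{beta_bounds}: f(lo)={f_lo:.3g}, f(hi)={f_hi:.3g}"
        )
    for _ in range(200):
        mid = np.sqrt(lo * hi)  # bisection on log(beta)
        f_mid = mean_fraction(mid)
        if abs(f_mid - target_fraction) <= tolerance:
            lo = hi = mid
            break
        if f_mid < target_fraction:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-12:
            break
    return model.with_beta(np.sqrt(lo * hi))
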