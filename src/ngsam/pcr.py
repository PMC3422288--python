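"""PCR molecule-count trajectories and coalescent genealogies of sampled
molecules.

A PCR is modelled as a branching process: in each cycle every molecule is
duplicated with probability equal to the per-cycle efficiency, so the count
follows ``N_i = N_{i-1} + Binomial(N_{i-1}, efficiency_i)``.

Forward simulation of every replication event is infeasible at realistic
molecule counts, so the genealogy of a small sample of final-pool molecules
is drawn *backward* over the cycles, conditional on the realized count
trajectory (the coalescent-style scheme of Weiss & von Haeseler).  Walking
from the last cycle to the first, each sampled lineage is one of that
cycle's freshly created product molecules with probability
``(N_i - N_{i-1}) / N_i``; products pick distinct template molecules
uniformly among the previous cycle's pool, a product lineage landing on a
template that already carries another sampled lineage coalesces with it, and
every product step adds one replication event to the lineage's branch
length.  Branch lengths therefore count replication events, the unit of
"time" on which mutations are later placed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ParameterError

# populations above this size use the binomial limit of the hypergeometric
# draw (numpy's exact sampler rejects populations > 1e9; the
# without-replacement correction is O(k^2/N) and negligible there)
_HYPERGEOM_LIMIT = 100_000_000


@dataclass(frozen=True)
class PCRParams:
    """Parameters of one PCR: starting molecules, per-cycle efficiency
    (scalar, or one value per cycle) and number of cycles."""

    n_start: int
    efficiency: float | Sequence[float] = 0.75
    n_cycles: int = 20

    def __post_init__(self):
        if self.n_start < 1:
            raise ParameterError("n_start must be >= 1")
        if self.n_cycles < 0:
            raise ParameterError("n_cycles must be >= 0")
        effs = self.efficiencies
        if len(effs) != self.n_cycles:
            raise ParameterError("need one efficiency per cycle")
        if any(not 0.0 <= e <= 1.0 for e in effs):
            raise ParameterError("efficiencies must lie in [0, 1]")

    @property
    def efficiencies(self) -> tuple[float, ...]:
        if np.isscalar(self.efficiency):
            return (float(self.efficiency),) * self.n_cycles
        return tuple(float(e) for e in self.efficiency)


@dataclass
class Trajectory:
    """Realized molecule counts ``N_0 ... N_n`` of one PCR."""

    counts: list[int]

    @property
    def n_cycles(self) -> int:
        return len(self.counts) - 1

    @property
    def final_count(self) -> int:
        return self.counts[-1]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("cycle\tmolecules\n")
            for i, n in enumerate(self.counts):
                fh.write(f"{i}\t{n}\n")


def simulate_counts(params: PCRParams, rng: np.random.Generator) -> Trajectory:
    """Simulate the branching-process count trajectory of a PCR."""
    counts = [params.n_start]
    n = params.n_start
    for eff in params.efficiencies:
        n = n + int(rng.binomial(n, eff))
        counts.append(n)
    return Trajectory(counts)


def expected_final_count(params: PCRParams) -> float:
    """Expected molecule count after amplification: ``S * prod(1 + eff_i)``."""
    out = float(params.n_start)
    for eff in params.efficiencies:
        out *= 1.0 + eff
    return out


@dataclass
class Genealogy:
    """Forest over sampled molecules with branch lengths in replication
    events.

    Nodes ``0 .. n_leaves-1`` are the sampled molecules (leaves); internal
    nodes are coalescence events.  ``children[v]`` lists ``(child,
    branch_length)`` pairs; ``roots`` lists ``(node, founder_id)`` pairs
    where ``founder_id`` identifies the distinct cycle-0 founder molecule of
    that tree.
    """

    children: list[list[tuple[int, int]]]
    n_leaves: int
    roots: list[tuple[int, int]]

    @property
    def n_trees(self) -> int:
        return len(self.roots)

    def leaf_founders(self) -> np.ndarray:
        """Founder id of every leaf, index-aligned with leaves."""
        out = np.full(self.n_leaves, -1, dtype=np.int64)
        for root, founder in self.roots:
            stack = [root]
            while stack:
                v = stack.pop()
                if v < self.n_leaves:
                    out[v] = founder
                stack.extend(c for c, _ in self.children[v])
        return out

    def leaf_depths(self) -> np.ndarray:
        """Total replication events on each leaf's root-to-leaf path."""
        out = np.zeros(self.n_leaves, dtype=np.int64)
        for root, _ in self.roots:
            stack = [(root, 0)]
            while stack:
                v, d = stack.pop()
                if v < self.n_leaves:
                    out[v] = d
                stack.extend((c, d + b) for c, b in self.children[v])
        return out

    def pairwise_distances(self) -> np.ndarray:
        """Replication-event path distance between every pair of leaves.

        Leaves in different trees (distinct founders) get distance -1.
        """
        k = self.n_leaves
        out = np.full((k, k), -1, dtype=np.int64)
        np.fill_diagonal(out, 0)

        def walk(v: int) -> dict[int, int]:
            if v < k:
                return {v: 0}
            below: dict[int, int] = {}
            for child, blen in self.children[v]:
                sub = {leaf: d + blen for leaf, d in walk(child).items()}
                for u, du in sub.items():
                    for w, dw in below.items():
                        out[u, w] = out[w, u] = du + dw
                below.update(sub)
            return below

        for root, _ in self.roots:
            walk(root)
        return out

    def to_newick(self) -> str:
        """Newick string (one tree per line) with integer branch lengths."""

        def render(v: int, blen: int | None) -> str:
            if v < self.n_leaves:
                label = f"L{v}"
            else:
                parts = ",".join(render(c, b) for c, b in self.children[v])
                label = f"({parts})"
            return label if blen is None else f"{label}:{blen}"

        return "\n".join(render(root, None) + ";" for root, _ in self.roots)


def _sample_distinct(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """k distinct uniform draws from range(n); exact for small n, rejection
    sampling for huge n (where collisions are vanishingly rare)."""
    if k > n:
        raise ParameterError("cannot sample more distinct molecules than exist")
    if k == 0:
        return np.empty(0, dtype=np.int64)
    if n <= max(1_000_000, 4 * k):
        return rng.choice(n, size=k, replace=False).astype(np.int64)
    ids = np.unique(rng.integers(0, n, size=k, dtype=np.int64))
    while len(ids) < k:
        extra = rng.integers(0, n, size=k - len(ids), dtype=np.int64)
        ids = np.unique(np.concatenate([ids, extra]))
    rng.shuffle(ids)
    return ids


def _n_products(k: int, n_new: int, n_total: int, rng: np.random.Generator) -> int:
    """How many of ``k`` sampled lineages are this cycle's product molecules
    (``n_new`` products among ``n_total``)."""
    if n_new == 0 or k == 0:
        return 0
    if n_total > _HYPERGEOM_LIMIT:
        return int(rng.binomial(k, n_new / n_total))
    return int(rng.hypergeometric(n_new, n_total - n_new, k))


def sample_genealogy(
    params: PCRParams,
    sample_size: int,
    trajectory: Trajectory,
    rng: np.random.Generator,
) -> Genealogy:
    """Sample the coalescent genealogy of ``sample_size`` final-pool
    molecules, conditional on the count trajectory.

    Raises :class:`ParameterError` if the sample exceeds the final pool.
    """
    counts = trajectory.counts
    if sample_size < 1:
        raise ParameterError("sample_size must be >= 1")
    if sample_size > counts[-1]:
        raise ParameterError(
            f"sample_size {sample_size} exceeds final pool {counts[-1]}"
        )

    children: list[list[tuple[int, int]]] = [[] for _ in range(sample_size)]
    # active lineage: [node_id, pending_branch_length]
    active = [[i, 0] for i in range(sample_size)]

    for i in range(trajectory.n_cycles, 0, -1):
        n_i, n_prev = counts[i], counts[i - 1]
        k = len(active)
        j = _n_products(k, n_i - n_prev, n_i, rng)
        prod_idx = rng.choice(k, size=j, replace=False) if j else np.empty(0, int)
        is_prod = np.zeros(k, dtype=bool)
        is_prod[prod_idx] = True
        # one replication event on every product lineage
        for a in prod_idx:
            active[a][1] += 1
        # place lineages on distinct cycle-(i-1) molecules: non-products are
        # those molecules themselves; products pick distinct templates,
        # independently -- a shared molecule id is a coalescence
        nonprod_ids = _sample_distinct(n_prev, k - j, rng)
        templ_ids = _sample_distinct(n_prev, int(j), rng)
        by_id: dict[int, list[int]] = {}
        it_non, it_tem = iter(nonprod_ids), iter(templ_ids)
        placed = [
            int(next(it_tem)) if is_prod[a] else int(next(it_non)) for a in range(k)
        ]
        for a, mol in enumerate(placed):
            by_id.setdefault(mol, []).append(a)
        new_active = []
        for mol, members in by_id.items():
            if len(members) == 1:
                new_active.append(active[members[0]])
            else:
                node = len(children)
                children.append([(active[a][0], active[a][1]) for a in members])
                new_active.append([node, 0])
        active = new_active

    # surviving lineages map to distinct founders among the initial molecules
    founders = _sample_distinct(counts[0], len(active), rng)
    # pending branch length above a root is the replication history between
    # the founder and the topmost coalescence; attach a unary founder node
    # if non-zero so leaf depths count every replication
    final_roots = []
    for idx, (node, pending) in enumerate(active):
        if pending > 0:
            top = len(children)
            children.append([(node, pending)])
            node = top
        final_roots.append((node, int(founders[idx])))
    return Genealogy(children=children, n_leaves=sample_size, roots=final_roots)
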