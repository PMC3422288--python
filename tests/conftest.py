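"""Shared fixtures and the forward-simulation oracle for PCR genealogies."""

from __future__ import annotations

import numpy as np
import pytest

from ngsam import MutationSpectrum, build_unrest, calibrate_scaling


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def unrest_model():
    """Default-spectrum UNREST model, uncalibrated (beta = 1)."""
    return build_unrest(MutationSpectrum.default())


@pytest.fixture(scope="session")
def calibrated_model(unrest_model):
    """Model calibrated to 5% mutated sites after a 10-cycle mutagenic PCR."""
    return calibrate_scaling(
        unrest_model, target_fraction=0.05, n_cycles=10,
        rng=np.random.default_rng(777),
    )


# ---------------------------------------------------------------------------
# forward parent-tracking PCR oracle (small instances only)

class ForwardGenealogy:
    """Summary of the genealogy of a sample from a fully tracked forward
    PCR simulation: every molecule and parent-child link is simulated."""

    def __init__(self, parents: list[int], sample: np.ndarray):
        self.parents = parents
        self.sample = sample

    def _path_to_root(self, m: int) -> list[int]:
        path = [m]
        while self.parents[path[-1]] >= 0:
            path.append(self.parents[path[-1]])
        return path

    def founders(self) -> list[int]:
        return [self._path_to_root(m)[-1] for m in self.sample]

    def n_founders(self) -> int:
        return len(set(self.founders()))

    def pairwise_distances(self) -> list[int]:
        """Replication-event distances for every sampled pair (sorted);
        -1 for pairs with different founders.  Each parent link counts one
        replication on the child side only."""
        out = []
        paths = [self._path_to_root(m) for m in self.sample]
        for i in range(len(paths)):
            for j in range(i + 1, len(paths)):
                pi, pj = paths[i], paths[j]
                si, sj = set(pi), set(pj)
                if pi[-1] != pj[-1]:
                    out.append(-1)
                    continue
                common = next(m for m in pi if m in sj)
                out.append(pi.index(common) + pj.index(common))
        return sorted(out)


def forward_parents(
    n_start: int, efficiency: float, n_cycles: int, rng: np.random.Generator
) -> list[int]:
    """Brute-force forward PCR: every molecule's parent link (-1 = founder).

    Molecules existing at the start of a cycle each duplicate at most once.
    """
    parents = [-1] * n_start
    for _cycle in range(n_cycles):
        n_now = len(parents)
        for m in range(n_now):
            if rng.random() < efficiency:
                parents.append(m)
    return parents


def forward_pcr(
    n_start: int, efficiency: float, n_cycles: int, sample_size: int,
    rng: np.random.Generator,
) -> ForwardGenealogy | None:
    """Forward simulation plus sampling; None if the final pool is too
    small (the caller conditions on pool size, as the backward path does)."""
    parents = forward_parents(n_start, efficiency, n_cycles, rng)
    if len(parents) < sample_size:
        return None
    sample = rng.choice(len(parents), size=sample_size, replace=False)
    return ForwardGenealogy(parents, sample)
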