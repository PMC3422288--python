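"""Internal helpers for DNA strings <-> integer-coded numpy arrays.

Bases are coded A=0, C=1, G=2, T=3 throughout the package; rate and
transition matrices use the same ordering.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(BASES.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0, C=1, G=2, T=3)."""
    arr = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"non-ACGT symbol in sequence: {bad!r}")
    return arr


def decode(arr: np.ndarray) -> str:
    """Decode a uint8 base array back to a DNA string."""
    return _DEC[arr].tobytes().decode()


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA string of the given length."""
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))
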