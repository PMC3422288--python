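"""Thin wrappers around edlib used by orientation, MSA and evaluation."""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class InfixAlignment:
    """Best alignment of a query inside a target (edlib HW mode).

    ``I`` ops consume query only, ``D`` ops consume target only.
    """

    distance: int
    target_start: int
    target_end: int  # inclusive, edlib convention
    cigar: list[tuple[int, str]]
    query_length: int

    @property
    def matches(self) -> int:
        return sum(n for n, op in self.cigar if op == "=")

    @property
    def columns(self) -> int:
        return sum(n for n, _ in self.cigar)

    @property
    def identity(self) -> float:
        """Matches per query base (penalizes unaligned query in NW-like
        sense; query is fully consumed in HW mode)."""
        return self.matches / max(self.query_length, 1)

    @property
    def column_identity(self) -> float:
        """Matches per alignment column (the aligned-portion identity)."""
        return self.matches / max(self.columns, 1)


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def align_infix(query: str, target: str) -> InfixAlignment:
    """Locate and align ``query`` inside ``target`` by edit distance."""
    res = edlib.align(query, target, mode="HW", task="path")
    start, end = res["locations"][0]
    return InfixAlignment(
        distance=res["editDistance"],
        target_start=start,
        target_end=end,
        cigar=parse_cigar(res["cigar"]),
        query_length=len(query),
    )


def edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def divergence(a: str, b: str) -> float:
    """Global edit distance normalized by the longer sequence."""
    return edit_distance(a, b) / max(len(a), len(b), 1)
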