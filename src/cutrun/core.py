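"""Shared genomic primitives: coordinates, junctions, and DNA sequence codecs.

All coordinates are 0-based, half-open ([start, end)), the BED convention.
Sequences are held either as Python strings or as numpy uint8 code arrays
with the mapping A=0, C=1, G=2, T=3, N(or anything else)=4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

BASES = "ACGTN"

_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

_DECODE_LUT = np.frombuffer(BASES.encode(), dtype=np.uint8)

#: complement in code space (A<->T, C<->G, N->N)
COMPLEMENT_CODES = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_COMPLEMENT_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back to an upper-case DNA string."""
    return _DECODE_LUT[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N fixed)."""
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT_CODES[codes[::-1]]


class InputError(ValueError):
    """Malformed or out-of-contract input (bad coordinates, rows, dialects)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored half-open coordinate range."""

    chrom: str
    start: int
    end: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise InputError("interval needs a chromosome name")
        if not (0 <= self.start < self.end):
            raise InputError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-"):
            raise InputError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """Half-open containment of a point."""
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, pos: int) -> int:
        """Distance from a point to the nearest base of the interval (0 if inside)."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - (self.end - 1)
        return 0


@dataclass(frozen=True)
class Junction:
    """A single translocation breakpoint (prey side) as a 0-based point."""

    chrom: str
    pos: int
    strand: str = "+"
    dataset: str = "default"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise InputError(f"junction position must be >= 0, got {self.pos}")
        if not self.dataset:
            raise InputError("junction dataset label must be non-empty")
        if self.strand not in ("+", "-", "."):
            raise InputError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class Breakpoint:
    """A patient breakpoint as a 0-based point coordinate."""

    chrom: str
    pos: int
    label: str = "breakpoint"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise InputError(f"breakpoint position must be >= 0, got {self.pos}")


def merge_intervals(starts_ends: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge half-open integer intervals into a disjoint sorted union."""
    ivs = sorted(starts_ends)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged
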