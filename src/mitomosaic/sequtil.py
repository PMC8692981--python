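"""Small shared helpers: sequences, rounding, and the Scaffold record."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero at ``ndigits`` decimals.

    Python's built-in ``round`` is banker's rounding; genome-fraction and
    composition percentages here follow the print convention (2.45 -> 2.5).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.447) -> str:
    """I.i.d. random DNA at the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def mutate_substitutions(
    rng: np.random.Generator, seq: str, rate: float
) -> tuple[str, int]:
    """Apply i.i.d. substitutions at ``rate``; returns (mutated, n_changed).

    Every selected position is forced to a *different* base, so ``n_changed``
    is the exact Hamming distance to the input.
    """
    if not 0 <= rate < 1:
        raise ValueError(f"substitution rate must be in [0,1), got {rate}")
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    alts = {b: [c.encode() for c in BASES if c != b] for b in BASES}
    for i in hit:
        arr[i] = alts[chr(arr[i][0])][rng.integers(3)]
    return arr.tobytes().decode(), len(hit)


@dataclass
class Scaffold:
    """A contiguous assembled unit with optional short-read depth."""

    id: str
    seq: str
    depth: float | None = None

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


@dataclass
class IntervalUnion:
    """Accumulates half-open intervals and reports total covered length."""

    intervals: list[tuple[int, int]] = field(default_factory=list)

    def add(self, start: int, end: int) -> None:
        if end > start:
            self.intervals.append((start, end))

    def covered(self) -> int:
        total, prev_end = 0, -1
        for s, e in sorted(self.intervals):
            s = max(s, prev_end)
            if e > s:
                total += e - s
                prev_end = e
            prev_end = max(prev_end, e)
        return total
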