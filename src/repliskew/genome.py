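"""Core circular-genome containers and coordinate arithmetic.

All internal coordinates are 0-based, half-open; circularity is handled by
the helpers here so downstream modules never do modular arithmetic inline.
GFF3 I/O converts to/from 1-based inclusive at the boundary (see io module).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class CircularGenome:
    """A circular nucleotide sequence.

    Parameters
    ----------
    id : sequence identifier.
    sequence : upper-case nucleotide string over {A, C, G, T, N}.
    circular : treat coordinates modulo the length (default True).
    """

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("genome sequence must be non-empty")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in sequence: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "CircularGenome":
        comp = str.maketrans("ACGTN", "TGCAN")
        return CircularGenome(self.id + "_rc", self.sequence.translate(comp)[::-1], self.circular)

    def rotate(self, delta: int) -> "CircularGenome":
        """Re-linearize the circle so old position ``delta`` becomes position 0."""
        d = delta % self.length
        return CircularGenome(self.id, self.sequence[d:] + self.sequence[:d], self.circular)


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval, 0-based half-open, on strand '+' or '-'.

    Wrap-around genes must be split at the origin before construction.
    """

    start: int
    end: int
    strand: str
    id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def circular_distance(a, b, length: int):
    """Shortest distance between positions on a circle of size ``length``.

    Accepts scalars or arrays; returns min(|a-b|, L-|a-b|).
    """
    d = np.abs(np.asarray(a) - np.asarray(b)) % length
    return np.minimum(d, length - d)


def n_windows(genome_length: int, window: int) -> int:
    """Number of non-overlapping windows tiling the circle.

    A residual arc shorter than half a window is merged into window 0
    (circularly adjacent to it) rather than tiled as a stub window.
    """
    if not 0 < window <= genome_length:
        raise ValueError("need 0 < window <= genome length")
    n_full, residual = divmod(genome_length, window)
    return n_full + (1 if residual >= window / 2 else 0)


def window_starts(genome_length: int, window: int, step: int | None = None) -> np.ndarray:
    """Start coordinates of (possibly overlapping) windows over the circle."""
    step = window if step is None else step
    if not (0 < step <= window):
        raise ValueError("need 0 < step <= window")
    if step == window:
        return np.arange(n_windows(genome_length, window)) * window
    starts = np.arange(0, genome_length, step)
    if genome_length % step and genome_length - starts[-1] < step / 2:
        starts = starts[:-1]
    return starts


def window_of(position, genome_length: int, window: int):
    """Index of the non-overlapping window containing each position.

    Residual-arc bases map to window 0 when the residual merged with it.
    """
    n = n_windows(genome_length, window)
    idx = (np.asarray(position) % genome_length) // window
    idx = np.where(idx >= n, 0, idx)  # merged residual arc wraps to window 0
    return idx if idx.ndim else int(idx)
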