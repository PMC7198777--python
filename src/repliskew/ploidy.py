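"""Chromosome copy-number estimation from flow-cytometry fluorescence.

DNA-stain fluorescence per cell is proportional to total DNA content, i.e.
(chromosome copies) x (genome size).  Comparing a sample's median
fluorescence to a reference species of known ploidy range [c_lo, c_hi] and
genome size therefore gives a copy-number range for the sample:

    k_b = round(rho * c_b * ref_genome / target_genome),   b in {lo, hi}

with rho the sample/reference median fluorescence ratio and rounding half
away from zero at each bound.  The median (not the mean) is used for rho
because cytometry fluorescence distributions are right-skewed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PloidyEstimate:
    """A copy-number range and the inputs that produced it."""

    fluorescence_ratio: float
    ref_copies: tuple
    ref_genome: int
    target_genome: int
    estimate: tuple

    def __post_init__(self) -> None:
        if self.fluorescence_ratio <= 0:
            raise ValueError("fluorescence_ratio must be positive")
        if self.ref_copies[0] > self.ref_copies[1]:
            raise ValueError("ref_copies range inverted")
        if self.ref_genome <= 0 or self.target_genome <= 0:
            raise ValueError("genome sizes must be positive")


def fluorescence_ratio(sample: np.ndarray, reference: np.ndarray) -> float:
    """Median fluorescence of the sample over that of the reference."""
    sample = np.asarray(sample, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if sample.size == 0 or reference.size == 0:
        raise ValueError("fluorescence lists must be non-empty")
    ref_median = float(np.median(reference))
    if ref_median <= 0:
        raise ValueError("reference median fluorescence must be positive")
    return float(np.median(sample)) / ref_median


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def estimate_ploidy(ratio: float, ref_copies: tuple, ref_genome: int,
                    target_genome: int) -> PloidyEstimate:
    """Copy-number range implied by a fluorescence ratio.

    ``ref_copies`` is the (low, high) chromosome-copy range of the reference
    species; genome sizes are in bp (any common unit works — only their
    ratio enters).
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if ref_genome <= 0 or target_genome <= 0:
        raise ValueError("genome sizes must be positive")
    c_lo, c_hi = ref_copies
    scale = ratio * ref_genome / target_genome
    estimate = (_round_half_away(scale * c_lo), _round_half_away(scale * c_hi))
    return PloidyEstimate(ratio, (c_lo, c_hi), ref_genome, target_genome, estimate)
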