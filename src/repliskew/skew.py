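"""Windowed and cumulative GC / CDS skew over circular genomes.

GC skew per window is (G - C)/(G + C) on the published strand; CDS skew is
the analogous orientation bias (F - R)/(F + R) of gene counts.  The running
sum of windowed skew (the cumulative profile) of a chromosome replicated
bidirectionally from a single origin traces a V (or inverted V): with a
G-rich leading strand the cumulative GC skew attains its global minimum at
the origin and its maximum at the terminus.  Shift-point detection exploits
this after mean-centering, which makes the call independent of where the
deposited sequence happens to start on the circle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import CircularGenome, GeneRecord, n_windows, window_of, window_starts

log = logging.getLogger(__name__)

PROFILE_KINDS = ("gc_skew", "cds_skew", "depth", "mfa_ratio")

DEFAULT_WINDOW = 10_000
V_SHAPE_R2_THRESHOLD = 0.90


@dataclass
class WindowedProfile:
    """Ordered per-window values over a circular coordinate system."""

    window: int
    step: int
    values: np.ndarray
    genome_length: int
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"kind must be one of {PROFILE_KINDS}")
        if self.kind in ("gc_skew", "cds_skew") and len(self.values):
            if np.nanmax(np.abs(self.values)) > 1 + 1e-12:
                raise ValueError("skew values must lie in [-1, 1]")

    @property
    def starts(self) -> np.ndarray:
        return window_starts(self.genome_length, self.window, self.step)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CumulativeProfile:
    """Running sum of a windowed profile; positions are window end coordinates."""

    positions: np.ndarray
    cum_values: np.ndarray
    parent: WindowedProfile = field(repr=False)


@dataclass
class ShiftPointCall:
    """Origin/terminus candidates from cumulative-skew extrema.

    ``regularity_index`` is the coefficient of determination of the best
    two-segment piecewise-linear circular fit to the mean-centered cumulative
    profile; profiles with regularity >= the threshold are flagged V-shaped.
    """

    ori_candidate: int | None
    ter_candidate: int | None
    regularity_index: float
    is_v_shaped: bool


def compute_gc_skew(genome: CircularGenome, window: int = DEFAULT_WINDOW,
                    step: int | None = None) -> WindowedProfile:
    """Windowed GC skew (G - C)/(G + C) on the published strand.

    Windows wrap the circle; N bases are excluded from both counts; a window
    with no G or C yields 0 (logged).
    """
    L = genome.length
    if not 0 < window <= L:
        raise ValueError("need 0 < window <= genome length")
    step = window if step is None else step
    seq = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)
    is_g = (seq == ord("G")).astype(np.int64)
    is_c = (seq == ord("C")).astype(np.int64)
    # circular prefix sums: duplicate the first window beyond the end
    g_ext = np.concatenate([is_g, is_g[:window]])
    c_ext = np.concatenate([is_c, is_c[:window]])
    cg = np.concatenate([[0], np.cumsum(g_ext)])
    cc = np.concatenate([[0], np.cumsum(c_ext)])
    starts = window_starts(L, window, step)
    if step == window:
        # non-overlapping partition of the circle; a residual arc shorter
        # than half a window merges into window 0
        ends = np.minimum(starts + window, L)
        g = cg[ends] - cg[starts]
        c = cc[ends] - cc[starts]
        residual = L % window
        if residual and residual < window / 2:
            covered = len(starts) * window
            g[0] += cg[L] - cg[covered]
            c[0] += cc[L] - cc[covered]
    else:
        # overlapping windows wrap past the end into the duplicated prefix
        g = cg[starts + window] - cg[starts]
        c = cc[starts + window] - cc[starts]
    tot = g + c
    empty = tot == 0
    if empty.any():
        log.info("GC skew: %d window(s) with no G/C bases set to 0", int(empty.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(empty, 0.0, (g - c) / np.where(empty, 1, tot))
    return WindowedProfile(window, step, skew, L, "gc_skew")


def compute_cds_skew(genes: list[GeneRecord], genome_length: int,
                     window: int = DEFAULT_WINDOW) -> WindowedProfile:
    """Windowed CDS skew (F - R)/(F + R) by gene midpoint.

    F and R count genes whose midpoint falls in the window on the '+' and
    '-' strand respectively; windows containing no gene midpoint yield 0.
    """
    n = n_windows(genome_length, window)
    fwd = np.zeros(n)
    rev = np.zeros(n)
    if not genes:
        log.info("CDS skew: empty gene list, all-zero profile")
    for gene in genes:
        w = window_of(gene.midpoint, genome_length, window)
        if gene.strand == "+":
            fwd[w] += 1
        else:
            rev[w] += 1
    tot = fwd + rev
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(tot == 0, 0.0, (fwd - rev) / np.where(tot == 0, 1, tot))
    return WindowedProfile(window, window, skew, genome_length, "cds_skew")


def cumulative(profile: WindowedProfile) -> CumulativeProfile:
    """Running sum of a windowed profile."""
    if len(profile) == 0:
        raise ValueError("profile is empty")
    cum = np.cumsum(profile.values)
    positions = (profile.starts + profile.window) % profile.genome_length
    return CumulativeProfile(positions, cum, profile)


def _v_fit_r2(values: np.ndarray, i_min: int, i_max: int) -> float:
    """R^2 of the circular two-segment linear interpolation through the extrema.

    The fitted profile rises linearly from the minimum to the maximum along
    one arc of the circle and falls linearly back along the other.
    """
    n = len(values)
    idx = np.arange(n)
    up_len = (i_max - i_min) % n
    down_len = n - up_len
    if up_len == 0 or down_len == 0:
        return 0.0
    lo, hi = values[i_min], values[i_max]
    pos_from_min = (idx - i_min) % n
    on_up = pos_from_min <= up_len
    fitted = np.where(
        on_up,
        lo + (hi - lo) * pos_from_min / up_len,
        hi - (hi - lo) * (pos_from_min - up_len) / down_len,
    )
    ss_res = float(np.sum((values - fitted) ** 2))
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def detect_shift_points(cum: CumulativeProfile,
                        r2_threshold: float = V_SHAPE_R2_THRESHOLD) -> ShiftPointCall:
    """Locate the skew shift points as extrema of the rotation-adjusted profile.

    The per-window mean skew is subtracted before summing, which makes the
    cumulative profile (up to an additive constant) invariant to the choice
    of linearization point on the circle; extrema positions then rotate with
    the genome.  For GC skew with a G-rich leading strand the origin is the
    global minimum and the terminus the global maximum.

    An all-zero parent profile yields no call (candidates ``None``).
    """
    parent = cum.parent
    if len(parent) < 8:
        raise ValueError("need at least 8 windows for shift-point detection")
    values = parent.values
    if np.all(values == 0):
        log.warning("shift-point detection: all-zero profile, no call")
        return ShiftPointCall(None, None, 0.0, False)
    adjusted = np.cumsum(values - values.mean())
    i_min = int(np.argmin(adjusted))
    i_max = int(np.argmax(adjusted))
    r2 = _v_fit_r2(adjusted, i_min, i_max)
    ori = int(cum.positions[i_min])
    ter = int(cum.positions[i_max])
    return ShiftPointCall(ori, ter, r2, bool(r2 >= r2_threshold))
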