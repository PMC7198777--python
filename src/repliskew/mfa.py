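"""Marker frequency analysis from exponential/stationary read depth.

The marker ratio R(x) compares normalized sequencing depth between an
exponentially growing (replicating) and a stationary (non-replicating)
population:

    R(x) = [exp_counts(x) / exp_total] / [stat_counts(x) / stat_total]

Chromosomes replicated bidirectionally from one origin show a V-shaped R
peaking at ori and dipping at ter; multifork growth pushes the ori/ter
ratio above 2, a polyploid population replicating only a few copies keeps
it near 1 while retaining the V, and asynchronous multi-origin replication
leaves R flat.  The module also provides the upstream read QC (quality
trimming) and bedGraph depth ingestion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import circular_distance, n_windows, window_of
from .skew import _v_fit_r2

log = logging.getLogger(__name__)

FINE_WINDOW = 1_000
COARSE_WINDOW = 100_000
COVERAGE_FLOOR = 100  # minimum reads per base reported by the QC check


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read with per-base Phred quality scores."""

    bases: str
    qualities: tuple

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError("bases and qualities must have equal length")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class TrimParams:
    """Read-trimming parameters: fixed end clips, quality floor, length floor."""

    min_phred: int = 30
    trim_5prime: int = 15
    trim_3prime: int = 2
    min_length: int = 100

    def __post_init__(self) -> None:
        if min(self.min_phred, self.trim_5prime, self.trim_3prime, self.min_length) < 0:
            raise ValueError("all trim parameters must be >= 0")


def _mott_segment(qualities: np.ndarray, min_phred: int) -> tuple[int, int]:
    """Best segment [i, j) under modified-Mott end trimming.

    Maximizes the running sum of (p_limit - p_err) over contiguous segments,
    where p_limit = 10^(-min_phred/10); equivalently trims low-quality ends.
    Ties broken toward the longer, then earlier, segment.
    """
    p_err = 10.0 ** (-qualities / 10.0)
    delta = 10.0 ** (-min_phred / 10.0) - p_err
    best_sum, best = 0.0, (0, 0)
    run_sum, run_start = 0.0, 0
    for i, d in enumerate(delta):
        run_sum += d
        if run_sum < 0:
            run_sum, run_start = 0.0, i + 1
            continue
        length = i + 1 - run_start
        if run_sum > best_sum or (run_sum == best_sum and length > best[1] - best[0]):
            best_sum, best = run_sum, (run_start, i + 1)
    return best


def trim_reads(reads: list[ReadRecord], params: TrimParams = TrimParams(),
               ) -> tuple[list[ReadRecord], dict]:
    """Clip fixed read ends, quality-trim the tails, drop short survivors.

    Per read: remove ``trim_5prime`` bases from the 5' end and
    ``trim_3prime`` from the 3' end, then keep the modified-Mott segment
    whose bases meet the Phred floor; reads shorter than ``min_length``
    after trimming are discarded.  Returns the retained reads and a QC
    summary with the retained fraction.
    """
    if not reads:
        log.warning("trim_reads: empty input")
        return [], {"n_in": 0, "n_out": 0, "retained_fraction": 0.0}
    out: list[ReadRecord] = []
    for read in reads:
        lo, hi = params.trim_5prime, len(read) - params.trim_3prime
        if hi - lo < params.min_length:
            continue
        quals = np.asarray(read.qualities[lo:hi], dtype=float)
        i, j = _mott_segment(quals, params.min_phred)
        if j - i < params.min_length:
            continue
        out.append(ReadRecord(read.bases[lo + i:lo + j], tuple(read.qualities[lo + i:lo + j])))
    qc = {"n_in": len(reads), "n_out": len(out),
          "retained_fraction": len(out) / len(reads)}
    return out, qc


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Load reads (Phred+33) from an uncompressed FASTQ file."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        records.append(ReadRecord(str(rec.seq),
                                  tuple(rec.letter_annotations["phred_quality"])))
    return records


@dataclass
class DepthProfile:
    """Per-window read counts for one sequencing sample."""

    window: int
    counts: np.ndarray
    total_reads: float
    genome_length: int
    label: str = "exponential"
    qc_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        expected = n_windows(self.genome_length, self.window)
        if len(self.counts) != expected:
            raise ValueError(
                f"expected {expected} windows for L={self.genome_length}, "
                f"window={self.window}; got {len(self.counts)}")
        # proxy for the per-base coverage floor: reads per window spread over
        # the window length
        per_base = self.counts / self.window
        self.qc_flags.setdefault("low_coverage", bool(per_base.mean() * self.window < COVERAGE_FLOOR))


def depth_from_bedgraph(path: str | Path, genome_length: int,
                        window: int = FINE_WINDOW, label: str = "exponential",
                        ) -> DepthProfile:
    """Aggregate a bedGraph (0-based half-open) into per-window read counts.

    Each interval's value is treated as a read count distributed pro rata
    over the bases it covers; overlapping intervals sum.  Intervals
    extending past the genome are a hard error naming the offending line.
    """
    n = n_windows(genome_length, window)
    counts = np.zeros(n)
    total = 0.0
    any_interval = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            if start < 0 or end > genome_length or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside "
                    f"[0, {genome_length})")
            any_interval = True
            total += value
            per_base = value / (end - start)
            w_first = int(window_of(start, genome_length, window))
            w_last = int(window_of(end - 1, genome_length, window))
            if w_first == w_last:
                counts[w_first] += value
            else:
                pos = start
                while pos < end:
                    w = int(window_of(pos, genome_length, window))
                    w_end = min(end, (pos // window + 1) * window)
                    counts[w] += per_base * (w_end - pos)
                    pos = w_end
    qc = {}
    if not any_interval:
        log.warning("depth_from_bedgraph: %s has no intervals", path)
        qc["empty_input"] = True
    return DepthProfile(window, counts, total, genome_length, label, qc)


@dataclass
class MFAProfile:
    """Marker ratio R(x) at a fine and a coarse window scale.

    Coarse values aggregate raw counts (not fine ratios) before dividing,
    which is the more stable estimator at low depth.  Windows where the
    stationary count is zero are masked.
    """

    genome_length: int
    fine_window: int
    coarse_window: int
    fine_values: np.ndarray
    fine_mask: np.ndarray
    coarse_values: np.ndarray
    coarse_mask: np.ndarray
    exp_fine: np.ndarray = field(repr=False)
    stat_fine: np.ndarray = field(repr=False)
    exp_total: float = 0.0
    stat_total: float = 0.0
    qc_flags: dict = field(default_factory=dict)

    @property
    def n_coarse(self) -> int:
        return len(self.coarse_values)

    def coarse_assignment(self) -> np.ndarray:
        """Coarse-window index of each fine window."""
        centers = (np.arange(len(self.exp_fine)) * self.fine_window
                   + self.fine_window / 2.0) % self.genome_length
        return np.asarray(window_of(centers, self.genome_length, self.coarse_window),
                          dtype=int)


def mfa_ratio(exp: DepthProfile, stat: DepthProfile,
              coarse_window: int = COARSE_WINDOW,
              mask_warn_fraction: float = 0.01) -> MFAProfile:
    """Normalized exponential/stationary depth ratio per window.

    R(x) = (exp counts / exp total) / (stat counts / stat total) at the fine
    window of the inputs; coarse windows sum the counts of their fine
    windows and take the same normalized ratio.
    """
    if exp.genome_length != stat.genome_length:
        raise ValueError("profiles cover different genome lengths")
    if exp.window != stat.window:
        raise ValueError("profiles use different window sizes")
    if exp.total_reads <= 0 or stat.total_reads <= 0:
        raise ValueError("total_reads must be positive in both samples")
    L, fine = exp.genome_length, exp.window
    norm = stat.total_reads / exp.total_reads
    fine_mask = stat.counts == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        fine_values = np.where(fine_mask, np.nan,
                               norm * exp.counts / np.where(fine_mask, 1, stat.counts))
    centers = (np.arange(len(exp.counts)) * fine + fine / 2.0) % L
    assign = np.asarray(window_of(centers, L, coarse_window), dtype=int)
    n_coarse = n_windows(L, coarse_window)
    exp_coarse = np.bincount(assign, weights=exp.counts, minlength=n_coarse)
    stat_coarse = np.bincount(assign, weights=stat.counts, minlength=n_coarse)
    coarse_mask = stat_coarse == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        coarse_values = np.where(coarse_mask, np.nan,
                                 norm * exp_coarse / np.where(coarse_mask, 1, stat_coarse))
    masked_frac = float(fine_mask.mean())
    qc = {"masked_fine_fraction": masked_frac}
    if masked_frac > mask_warn_fraction:
        log.warning("mfa_ratio: %.1f%% of fine windows masked", 100 * masked_frac)
        qc["high_masked_fraction"] = True
    return MFAProfile(L, fine, coarse_window, fine_values, fine_mask,
                      coarse_values, coarse_mask, exp.counts.copy(),
                      stat.counts.copy(), exp.total_reads, stat.total_reads, qc)


@dataclass
class OriginCall:
    """Origin position, peak/trough ratio and replication-mode label."""

    origin_position: int | None
    peak_trough_ratio: float
    mode: str  # single_origin_V | flat_multi_origin | indeterminate
    bootstrap_ci: tuple
    v_fit_r2: float = float("nan")
    p_flat: float = float("nan")
    diagnostics: dict = field(default_factory=dict)


def _circular_moving_average(values: np.ndarray, span: int) -> np.ndarray:
    if span <= 1:
        return values.copy()
    kernel = np.ones(span) / span
    padded = np.concatenate([values[-(span // 2):], values, values[:span - span // 2 - 1]])
    return np.convolve(padded, kernel, mode="valid")


def _peak_trough(coarse_values: np.ndarray, span: int) -> tuple[int, int, float, np.ndarray]:
    """Smoothed peak/trough indices and attenuation-corrected ratio.

    A boxcar of width W flattens a circular triangular profile of
    peak-to-trough amplitude A to A*(1 - W/L), clipping peak and trough by
    A*W/(2L) each; the correction inverts that, so the reported ratio is an
    unbiased vertex estimate for V-shaped profiles and a no-op for span 1.
    """
    smoothed = _circular_moving_average(coarse_values, span)
    i_max = int(np.argmax(smoothed))
    i_min = int(np.argmin(smoothed))
    window_frac = min(span / len(coarse_values), 0.5)
    amplitude = (smoothed[i_max] - smoothed[i_min]) / (1.0 - window_frac)
    clip = amplitude * window_frac / 2.0
    ratio = float((smoothed[i_max] + clip) / (smoothed[i_min] - clip))
    return i_max, i_min, ratio, smoothed


def _refine_origin(values: np.ndarray, coarse_window: int, genome_length: int,
                   resolution: int) -> int:
    """Sub-window origin estimate by a circular V-vertex grid fit.

    For each candidate vertex x0 on a fine grid, regress the coarse ratio
    profile on the normalized ori distance d(x) = 2*dist(x, x0)/L and score
    by the explained sum of squares; the origin is the candidate with the
    strongest negative slope (ratio falling away from the peak).  The
    antipodal vertex gives a mirrored fit with identical R^2, so the slope
    sign disambiguates ori from ter.
    """
    n = len(values)
    centers = (np.arange(n) * coarse_window + coarse_window / 2.0) % genome_length
    candidates = np.arange(0, genome_length, resolution, dtype=float)
    d = 2.0 * circular_distance(centers[None, :], candidates[:, None],
                                genome_length) / genome_length
    y = values - values.mean()
    dc = d - d.mean(axis=1, keepdims=True)
    cov = dc @ y
    var = np.einsum("ij,ij->i", dc, dc)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where((cov < 0) & (var > 0), cov ** 2 / np.where(var > 0, var, 1), -np.inf)
    return int(candidates[int(np.argmax(score))])


def detect_origin(mfa: MFAProfile, smooth_span: int = 5,
                  v_r2_threshold: float = 0.5, n_bootstrap: int = 200,
                  ci_level: float = 0.95, seed: int = 0,
                  max_masked_fraction: float = 0.2) -> OriginCall:
    """Locate the replication origin and classify the replication mode.

    The coarse ratio profile is smoothed with a circular moving average for
    the peak/trough ratio; the origin position itself is refined below the
    coarse-window granularity with a circular V-vertex grid fit
    (:func:`_refine_origin`).  Classification combines a
    two-segment circular V fit (R^2 against ``v_r2_threshold``) with a
    flatness test: because a peak/trough ratio is a max/min statistic it is
    biased above 1 on a perfectly flat profile, so departure from flatness
    is judged by a seeded permutation test (fine windows shuffled around
    the circle, peak/trough detection re-run) rather than by whether a
    naive interval covers 1.  ``single_origin_V`` requires both an adequate
    V fit and a significant peak (p <= 1 - ci_level); a non-significant
    peak yields ``flat_multi_origin``; a significant peak with a poor V fit
    is ``indeterminate``.

    The reported ``bootstrap_ci`` is the basic bootstrap interval for the
    peak/trough ratio under within-coarse-window resampling of fine
    windows, with the detection re-run per replicate.
    """
    n = mfa.n_coarse
    if n < 20:
        raise ValueError("need at least 20 coarse windows")
    masked_frac = float(mfa.coarse_mask.mean())
    if masked_frac > max_masked_fraction:
        log.warning("detect_origin: %.0f%% coarse windows masked", 100 * masked_frac)
        return OriginCall(None, float("nan"), "indeterminate", (float("nan"),) * 2,
                          diagnostics={"masked_fraction": masked_frac})
    values = mfa.coarse_values.copy()
    if mfa.coarse_mask.any():
        values[mfa.coarse_mask] = np.nanmean(values)
    i_max, i_min, theta, smoothed = _peak_trough(values, smooth_span)
    origin = _refine_origin(values, mfa.coarse_window, mfa.genome_length,
                            resolution=mfa.fine_window)
    r2 = _v_fit_r2(values, i_min, i_max)

    rng = np.random.default_rng(seed)
    assign = mfa.coarse_assignment()
    order = np.argsort(assign, kind="stable")
    sizes = np.bincount(assign, minlength=n)
    group_start = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    norm = mfa.stat_total / mfa.exp_total
    replicates = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        pick = order[group_start[assign] + rng.integers(0, sizes[assign])]
        exp_c = np.bincount(assign, weights=mfa.exp_fine[pick], minlength=n)
        stat_c = np.bincount(assign, weights=mfa.stat_fine[pick], minlength=n)
        bad = stat_c == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = norm * exp_c / np.where(bad, 1, stat_c)
        if bad.any():
            vals[bad] = np.nanmean(np.where(bad, np.nan, vals))
        replicates[b] = _peak_trough(vals, smooth_span)[2]
    alpha = 1.0 - ci_level
    q_lo, q_hi = np.quantile(replicates, [alpha / 2, 1 - alpha / 2])
    ci = (2 * theta - q_hi, 2 * theta - q_lo)  # basic bootstrap interval

    # permutation null: scramble fine windows around the circle, re-detect
    n_fine = len(mfa.exp_fine)
    null = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        perm = rng.permutation(n_fine)
        exp_c = np.bincount(assign, weights=mfa.exp_fine[perm], minlength=n)
        stat_c = np.bincount(assign, weights=mfa.stat_fine[perm], minlength=n)
        bad = stat_c == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = norm * exp_c / np.where(bad, 1, stat_c)
        if bad.any():
            vals[bad] = np.nanmean(np.where(bad, np.nan, vals))
        null[b] = _peak_trough(vals, smooth_span)[2]
    p_flat = float((1 + np.sum(null >= theta)) / (1 + n_bootstrap))

    if p_flat > alpha:
        mode = "flat_multi_origin"
    elif r2 >= v_r2_threshold:
        mode = "single_origin_V"
    else:
        mode = "indeterminate"
    return OriginCall(origin, theta, mode, ci, r2, p_flat,
                      diagnostics={"masked_fraction": masked_frac,
                                   "smooth_span": smooth_span,
                                   "n_bootstrap": n_bootstrap})


def ori_ter_ratio(mfa: MFAProfile, origin: int) -> float:
    """Coarse-window marker ratio at the origin over the antipodal window."""
    L = mfa.genome_length
    if not 0 <= origin < L:
        raise ValueError("origin must lie in [0, genome_length)")
    i = int(window_of(origin, L, mfa.coarse_window))
    j = int(window_of((origin + L // 2) % L, L, mfa.coarse_window))
    i = _nearest_unmasked(mfa, i)
    j = _nearest_unmasked(mfa, j)
    return float(mfa.coarse_values[i] / mfa.coarse_values[j])


def _nearest_unmasked(mfa: MFAProfile, idx: int) -> int:
    if not mfa.coarse_mask[idx]:
        return idx
    n = mfa.n_coarse
    for step in range(1, n):
        for cand in ((idx + step) % n, (idx - step) % n):
            if not mfa.coarse_mask[cand]:
                log.warning("ori_ter_ratio: window %d masked, using %d", idx, cand)
                return cand
    raise ValueError("all coarse windows masked")
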