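"""Synthetic genomes, annotations, coverage and cytometry data.

Generators that emulate the statistical structure the analysis stages
assume: strand-biased base composition switching at ori/ter, leading-strand
gene-orientation bias, population read-depth profiles under three
replication modes, and per-cell fluorescence proportional to DNA content.
Every generator is deterministic under its seed.

Replication modes
-----------------
``single_origin``
    A polyploid population in which a fraction ``r`` of chromosome copies
    carry one bidirectional fork pair started at ``ori_position``, with fork
    progress uniform on [0, 1].  Relative copy number is m(d) = 1 + r(1-d)
    with d the normalized ori distance (0 at ori, 1 at ter), so the ori/ter
    ratio is 1 + r.
``multifork``
    Overlapping rounds of replication in an exponentially-aged population;
    m(d) = 2^{k(1-d)} where ``k`` is the ratio of replication time to
    doubling time.  The ori/ter ratio is 2^k (> 2 when k > 1).
``multi_origin_async``
    Asynchronous initiation from many dispersed sites; copy number is flat
    across the chromosome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .genome import CircularGenome, GeneRecord, circular_distance, n_windows
from .mfa import DepthProfile

MODES = ("single_origin", "multifork", "multi_origin_async")


@dataclass(frozen=True)
class ReplicationModel:
    """Parameters of a population replication process.

    mode : one of ``single_origin``, ``multifork``, ``multi_origin_async``.
    genome_length : chromosome size L in bp.
    ori_position : replication origin (ignored for multi_origin_async).
    replicating_fraction : fraction r of copies replicating (single_origin).
    fork_intensity : multifork overlap parameter k >= 0 (multifork).
    ploidy : chromosome copies per cell, N >= 1.
    """

    mode: str
    genome_length: int
    ori_position: int = 0
    replicating_fraction: float = 0.0
    fork_intensity: float = 0.0
    ploidy: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0 <= self.ori_position < self.genome_length:
            raise ValueError("need 0 <= ori_position < genome_length")
        if not 0.0 <= self.replicating_fraction <= 1.0:
            raise ValueError("replicating_fraction must be in [0, 1]")
        if self.fork_intensity < 0:
            raise ValueError("fork_intensity must be >= 0")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")


@dataclass(frozen=True)
class SkewedGenomeSpec:
    """Recipe for a circular genome with leading-strand G enrichment.

    On the replichore running (in ascending circular coordinates) from
    ``ori_position`` to ``ter_position`` the published strand is the leading
    strand: G is emitted with probability gc/2*(1+s) and C with gc/2*(1-s);
    on the other replichore the bias is reversed.  A and T split the
    remaining probability evenly.
    """

    length: int
    ori_position: int
    ter_position: int
    skew_strength: float = 0.3
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.ori_position == self.ter_position:
            raise ValueError("ori and ter must differ")
        for p in (self.ori_position, self.ter_position):
            if not 0 <= p < self.length:
                raise ValueError("ori/ter must lie in [0, length)")
        if not 0.0 <= self.skew_strength <= 1.0:
            raise ValueError("skew_strength must be in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")


@dataclass(frozen=True)
class FlowSimSpec:
    """Recipe for a per-cell fluorescence sample.

    Fluorescence scales with DNA per cell (copies_mean x genome_size); values
    are lognormal with the given median and coefficient of variation.
    """

    n_cells: int
    copies_mean: float
    genome_size: int
    cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.copies_mean <= 0 or self.genome_size <= 0:
            raise ValueError("copies_mean and genome_size must be positive")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")


def on_first_replichore(position, ori: int, ter: int, length: int):
    """True where ``position`` lies on the arc ori -> ter (ascending, circular)."""
    arc = (ter - ori) % length
    return ((np.asarray(position) - ori) % length) < arc


def generate_skewed_genome(spec: SkewedGenomeSpec) -> tuple[CircularGenome, dict]:
    """Draw a circular genome with GC skew switching at ori and ter.

    Returns the genome and a truth record ``{"ori": ..., "ter": ...}``.
    """
    rng = np.random.default_rng(spec.seed)
    pos = np.arange(spec.length)
    leading = on_first_replichore(pos, spec.ori_position, spec.ter_position, spec.length)
    gc, s = spec.gc_content, spec.skew_strength
    at = (1.0 - gc) / 2.0
    # base order: A, C, G, T
    p_fwd = np.array([at, gc / 2 * (1 - s), gc / 2 * (1 + s), at])
    p_rev = np.array([at, gc / 2 * (1 + s), gc / 2 * (1 - s), at])
    u = rng.random(spec.length)
    cdf_fwd = np.cumsum(p_fwd)
    cdf_rev = np.cumsum(p_rev)
    idx = np.where(leading,
                   np.searchsorted(cdf_fwd, u, side="right"),
                   np.searchsorted(cdf_rev, u, side="right"))
    idx = np.clip(idx, 0, 3)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode("ascii")
    genome = CircularGenome(f"synthetic_L{spec.length}_s{s}", seq)
    truth = {"ori": spec.ori_position, "ter": spec.ter_position,
             "skew_strength": s, "gc_content": gc, "seed": spec.seed}
    return genome, truth


def generate_annotations(genome_truth: dict, genome_length: int, n_genes: int,
                         leading_bias: float = 0.8, seed: int = 0,
                         mean_gene_length: int = 900) -> list[GeneRecord]:
    """Place genes uniformly with a leading-strand orientation bias.

    Each gene is oriented with the leading strand of its replichore with
    probability ``leading_bias``.  On the replichore ori -> ter the leading
    strand is '+'; on the other it is '-'.  Overlap between genes is not
    prevented.  ``n_genes = 0`` returns an empty list.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if not 0.0 <= leading_bias <= 1.0:
        raise ValueError("leading_bias must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ori, ter = genome_truth["ori"], genome_truth["ter"]
    genes: list[GeneRecord] = []
    for i in range(n_genes):
        length = max(60, int(rng.normal(mean_gene_length, mean_gene_length / 3)))
        length = min(length, genome_length - 1)
        start = int(rng.integers(0, genome_length - length))
        mid = start + length // 2
        leading_strand = "+" if on_first_replichore(mid, ori, ter, genome_length) else "-"
        if rng.random() < leading_bias:
            strand = leading_strand
        else:
            strand = "-" if leading_strand == "+" else "+"
        genes.append(GeneRecord(start, start + length, strand, id=f"gene{i:05d}"))
    return genes


def expected_relative_copy_number(model: ReplicationModel, position) -> np.ndarray | float:
    """Expected relative copy number m at a genomic position.

    With d = 2 * circular_distance(position, ori) / L in [0, 1]:

    * single_origin:      m(d) = 1 + r * (1 - d)
    * multifork:          m(d) = 2 ** (k * (1 - d))
    * multi_origin_async: m = 1 everywhere

    Normalized so the terminus value is 1 for the first two modes.
    """
    pos = np.asarray(position, dtype=float)
    if model.mode == "multi_origin_async":
        out = np.ones_like(pos)
        return out if out.ndim else 1.0
    d = 2.0 * circular_distance(pos, model.ori_position, model.genome_length) / model.genome_length
    if model.mode == "single_origin":
        out = 1.0 + model.replicating_fraction * (1.0 - d)
    else:  # multifork
        out = 2.0 ** (model.fork_intensity * (1.0 - d))
    return out if out.ndim else float(out)


def sample_copy_number(model: ReplicationModel, position: int, n_chromosomes: int,
                       seed: int = 0) -> float:
    """Monte-Carlo mean copy number at ``position`` from explicit fork states.

    Independent check on the closed forms in
    :func:`expected_relative_copy_number`; draws per-chromosome fork
    progress and counts whether the locus has been duplicated.
    """
    rng = np.random.default_rng(seed)
    L = model.genome_length
    d = 2.0 * float(circular_distance(position, model.ori_position, L)) / L
    if model.mode == "multi_origin_async":
        return 1.0
    if model.mode == "single_origin":
        replicating = rng.random(n_chromosomes) < model.replicating_fraction
        progress = rng.random(n_chromosomes)
        copies = 1.0 + (replicating & (progress >= d))
        return float(np.mean(copies))
    # multifork: steady-state exponential culture, cell age a in [0,1) with
    # density 2 ln2 * 2^{-a} (doubling time 1); a locus at normalized ori
    # distance d is duplicated k*(1-d) generations before division, so a
    # cell of age a holds 2^{floor(a + k*(1-d))} copies (1 at ter).
    u = rng.random(n_chromosomes)
    a = -np.log2(1.0 - u / 2.0)
    copies = 2.0 ** np.floor(a + model.fork_intensity * (1.0 - d))
    return float(np.mean(copies))


def simulate_depth_profiles(model: ReplicationModel, window: int = 1000,
                            mean_depth: float = 500.0, seed: int | None = None):
    """Simulate exponential- and stationary-phase window read counts.

    Exponential counts ~ Poisson(mean_depth * m / mean(m)) where m is the
    mode's relative copy number; stationary counts ~ Poisson(mean_depth)
    (non-replicating, flat).  Poisson noise models the counting error of
    deep sequencing.
    """
    if mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    L = model.genome_length
    n = n_windows(L, window)
    centers = (np.arange(n) * window + window / 2.0) % L
    m = np.asarray(expected_relative_copy_number(model, centers), dtype=float)
    lam_exp = mean_depth * m / m.mean()
    exp_counts = rng.poisson(lam_exp)
    stat_counts = rng.poisson(mean_depth, size=n)
    exp = DepthProfile(window, exp_counts, int(exp_counts.sum()), L, "exponential")
    stat = DepthProfile(window, stat_counts, int(stat_counts.sum()), L, "stationary")
    return exp, stat


def simulate_flow_cytometry(spec: FlowSimSpec) -> np.ndarray:
    """Per-cell fluorescence, lognormal with median ~ copies x genome size.

    cv = 0 returns all values exactly at the median.  The absolute scale is
    arbitrary (instrument units); only ratios between samples are meaningful.
    """
    median = spec.copies_mean * spec.genome_size * 1e-6
    if spec.cv == 0:
        return np.full(spec.n_cells, median)
    sigma = np.sqrt(np.log1p(spec.cv ** 2))
    rng = np.random.default_rng(spec.seed)
    return median * np.exp(sigma * rng.standard_normal(spec.n_cells))


def write_truth(truth: dict, path: str | Path) -> None:
    """Write a generator truth record as a JSON sidecar."""
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def model_to_dict(model: ReplicationModel) -> dict:
    return asdict(model)
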