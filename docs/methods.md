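# Methods

## Coordinate conventions

All internal coordinates are 0-based, half-open, on a circular chromosome
of length L; GFF3 I/O converts to/from 1-based inclusive at the boundary,
bedGraph is read and written 0-based half-open. Circular distances are
d(a, b) = min(|a − b|, L − |a − b|). Windows tile the circle
non-overlapping by default; when L is not a multiple of the window size, a
residual arc shorter than half a window is merged into window 0 (its
circular neighbour), otherwise it becomes a short final window. The default
skew window is 10 kb for genomes ≥ 1 Mb; MFA uses 1-kb fine and 100-kb
coarse windows. All sizes are configurable.

## Skew profiles and shift-point detection

GC skew per window is S = (n_G − n_C)/(n_G + n_C) on the published strand,
with N bases excluded from both counts and 0/0 windows set to 0 (logged) so
cumulative sums stay total. CDS skew is (F − R)/(F + R), where F and R
count genes by strand, each gene assigned to the window containing its
midpoint — midpoint assignment avoids double-counting genes spanning window
borders.

The cumulative profile of a circular genome depends on where the deposited
sequence starts, so before extremum detection the per-window mean skew is
subtracted; the mean-centered cumulative sum is then rotation-invariant up
to an additive constant, and the detected extrema rotate exactly with the
genome. Under the common bacterial convention of a G-rich leading strand,
the cumulative GC skew attains its minimum at the origin and its maximum at
the terminus; if a genome has the opposite polarity the labels swap, which
is a reporting convention, not an inference.

The regularity index R²_V is the coefficient of determination of the
two-segment piecewise-linear circular interpolation anchored at the two
extrema (rising min→max along one arc, falling along the other). A profile
is called V-shaped when R²_V ≥ 0.90. The threshold separates strongly
skewed genomes (generator skew strength s ≥ 0.1 gives R²_V near 1) from
white-noise profiles, whose mean-centered cumulative sum is a random-walk
bridge; the test suite verifies that such null profiles exceed the
threshold in at most 5% of seeds. It is exposed as a parameter.

## Marker frequency analysis

The marker ratio is computed per fine window as
R(x) = [n_exp(x)/N_exp] / [n_stat(x)/N_stat]; coarse windows aggregate raw
counts first and then take the same normalized ratio, which is more stable
at low depth than averaging fine-window ratios. Fine windows with zero
stationary counts are masked (a warning is raised above 1% masked); a
coarse masked fraction above 20% aborts origin detection as indeterminate.

Origin detection smooths the coarse profile with a circular moving average
(default span 5 coarse windows) and reports:

* **origin_position** — not the smoothed argmax (whose granularity is one
  coarse window, 100 kb) but a circular V-vertex fit: for every candidate
  vertex on the fine grid, the coarse profile is regressed on the
  normalized ori distance δ(x) = 2 d(x, x0)/L and the candidate with the
  largest explained sum of squares among negative slopes is taken. The
  antipodal point gives a mirrored fit with identical R², so the slope sign
  distinguishes ori from ter. On simulated data (L = 3 Mb, 500
  reads/kb-window) this localizes the origin within ±2% of L down to
  r = 0.1.
* **peak_trough_ratio** — smoothed max over smoothed min, corrected for
  boxcar attenuation: a boxcar of width W flattens a circular triangular
  profile of amplitude A to A(1 − W/L), so the estimate inverts that
  factor. At the default span the uncorrected ratio would underestimate
  1 + r by W/L ≈ 17%; the test suite verifies that the corrected median
  recovers r within ±20% across r ∈ {0.1, 0.3, 0.5}.
* **mode** — `single_origin_V` requires a two-segment circular V fit with
  R² ≥ 0.5 *and* a significant departure from flatness; `flat_multi_origin`
  is returned when flatness cannot be rejected; a significant peak without
  an adequate V fit is `indeterminate`.

Flatness is judged by a seeded permutation test: fine windows are shuffled
around the circle (destroying any spatial structure while preserving the
count distribution), the full smoothing + peak/trough detection is re-run
per permutation (default 200), and the p-value is the fraction of
permutation ratios at or above the observed one. A permutation null is used
deliberately instead of asking whether a bootstrap interval covers 1: the
peak/trough ratio is a max/min statistic, biased above 1 on any noisy flat
profile, and intervals centered on it systematically exclude 1 even when
the profile is flat. A basic bootstrap interval for the peak/trough ratio
(fine windows resampled with replacement within each coarse window,
detection re-run per replicate) is still reported as the uncertainty on the
ratio itself.

The ori/ter ratio is the coarse-window ratio value at the window containing
the origin over the antipodal window; if either is masked the nearest
unmasked neighbour is used and flagged.

### Read trimming

Reads are clipped by fixed amounts at the ends (defaults 15 nt from the 5′
end, 2 nt from the 3′ end), then quality-trimmed with modified-Mott end
trimming: with error probabilities p_i = 10^(−q_i/10) and limit
p₀ = 10^(−30/10), the retained segment maximizes Σ (p₀ − p_i), ties broken
toward the longer then earlier segment. Reads shorter than 100 nt after
trimming are discarded — the length rule is interpreted as a post-trim
minimum, the only reading consistent with quality control. Alignment is out
of scope; depth is consumed as bedGraph, with interval values distributed
pro rata over the bases they cover.

## Ploidy estimation

The fluorescence ratio ρ is the ratio of sample to reference medians — the
median because cytometry fluorescence is right-skewed and the appropriate
summary is not otherwise determined. Copy-number bounds are
k_b = round_half_away_from_zero(ρ · c_b · G_ref / G_target) for each bound
c_b of the reference ploidy range. Rounding half away from zero reproduces
the canonical worked examples (16–32 and 5–11 copies); for the 3.9-Mb
comparison it yields an upper bound of 33 where ceiling would give 34 — the
convention is applied uniformly rather than per-case. Cell-volume
comparisons are descriptive ratios only; no model is fitted.

## The simulator

The simulator generates exactly the statistical structure the analyses
assume, which makes the tests sharp but bounds what they show about real
data.

* **Genomes**: on the replichore from ori to ter (ascending coordinates)
  the published strand emits G with probability (gc/2)(1 + s) and C with
  (gc/2)(1 − s); the bias is mirrored on the other replichore; A/T split
  the remainder evenly. Defaults s = 0.3, gc = 0.5. Real genomes add
  local compositional heterogeneity, repeats and horizontally acquired
  islands that blur the V; passing tests demonstrate correctness of the
  detection arithmetic, not robustness to such features.
* **Gene sets**: genes placed uniformly (length ~ N(900, 300) bp, floored
  at 60 bp), oriented with their replichore's leading strand with
  probability p (default 0.8, in the range of reported leading-strand
  biases). Gene overlap is not prevented.
* **Coverage**: window counts are Poisson with mean
  depth · m(δ)/mean(m) for the exponential sample and flat Poisson for the
  stationary sample. The single-origin model assumes fork progress uniform
  on [0, 1] — the minimal assumption that reproduces a linear V; the
  multifork model uses the exponential steady-state age structure
  (m(δ) = 2^{k(1−δ)}), cross-checked in the tests against an explicit
  Monte-Carlo sampler of cell ages (age density 2 ln2 · 2^(−a), copies
  2^⌊a + k(1−δ)⌋). Poisson (not negative-binomial) noise is adequate at
  the coverage this pipeline expects (≥ 100 reads per base); real coverage
  additionally carries GC bias and mappability structure that the
  simulator deliberately omits.
* **Cytometry**: per-cell fluorescence is lognormal with median
  proportional to copies × genome size and a given coefficient of
  variation (default 0.3, typical of log-phase populations without
  gating); instrument gating, debris and doublets are not modelled.

Every generator is deterministic given its seed; identical spec + seed
give bit-identical output.

## Problem sizes and defaults

Simulation-backed checks run at L = 3 Mb with 1-kb windows and 500
reads/window (2,000 for the small-r polyploid case, where the V amplitude
is 3%), 20 seeds per condition — sizes chosen to match the regime the
method targets (Mb-scale genomes, deep coverage) while keeping the full
suite fast. Bootstrap and permutation replicates default to 200; the CI
level is 95%.

## Known limitations

* The skew sign convention assumes a G-rich leading strand; genomes with
  inverted polarity yield swapped ori/ter labels.
* Shift-point detection returns exactly one ori/ter pair; genomes with
  multiple compositional switch points (e.g. large inversions) will fit
  poorly and score a low R²_V rather than being decomposed.
* MFA mode classification is calibrated for ≥ 20 coarse windows; short
  plasmid-scale replicons are rejected rather than classified.
* The ploidy estimate propagates no uncertainty from the reference ploidy
  range other than evaluating both bounds.
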