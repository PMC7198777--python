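# repliskew

Replication-origin analysis for circular bacterial genomes, with the
polyploid cyanobacteria in mind: many of these species carry tens of copies
of the same chromosome, some lack the canonical initiator gene *dnaA*
altogether, and whether a chromosome is replicated from one origin or many
leaves distinct fingerprints in both its base composition and its
sequencing coverage. `repliskew` computes those fingerprints and classifies
them:

* **GC / CDS skew profiling** — windowed GC skew S = (G − C)/(G + C) and
  gene-orientation (CDS) skew, their cumulative profiles Σᵢ Sᵢ, detection of
  the ori/ter shift points as the extrema of the rotation-adjusted
  cumulative profile, and a regularity index R²_V scoring how V-shaped the
  profile is.
* **Marker frequency analysis (MFA)** — the normalized depth ratio
  R(x) = [n_exp(x)/N_exp] / [n_stat(x)/N_stat] between an exponentially
  growing and a stationary population, at 1-kb and 100-kb windows; origin
  localization, the ori/ter ratio, and classification into
  `single_origin_V`, `flat_multi_origin` or `indeterminate`. Read-quality
  trimming (Phred floor 30, fixed end clips, 100-nt length floor) and
  bedGraph depth ingestion are included.
* **Ploidy estimation** — chromosome copy number from flow-cytometry
  fluorescence relative to a reference species:
  k_b = round(ρ · c_b · G_ref / G_target) for each bound b of the reference
  ploidy range.
* **A replication simulator** — synthetic genomes with skew switching at
  ori/ter, biased gene sets, Poisson coverage under three population
  replication models (single origin with replicating fraction *r*:
  m(δ) = 1 + r(1 − δ); multifork with intensity *k*: m(δ) = 2^{k(1−δ)};
  flat asynchronous multi-origin), and lognormal per-cell fluorescence —
  so every stage is testable end to end without external data.

## Worked example

```sh
python examples/02_marker_frequency_analysis.py
```

```
single origin, r=0.3         mode=single_origin_V    origin=2,994,000 ori/ter=1.28 peak/trough=1.29
multifork, k=1.5             mode=single_origin_V    origin=    1,000 ori/ter=2.65 peak/trough=2.90
asynchronous multi-origin    mode=flat_multi_origin  origin=1,550,000 ori/ter=0.99 peak/trough=1.01
```

Each line simulates exponential/stationary coverage for a 3-Mbp chromosome
(1-kb windows, 500 reads/window) and runs the MFA pipeline. The true origin
is at position 0, so 2,994,000 is 6 kb away around the circle. The
single-origin population replicating 30% of its copies shows ori/ter ≈ 1.3
(= 1 + r); multifork growth with k = 1.5 gives a ratio near 2.65 (window
averaging slightly attenuates the point value 2^1.5 ≈ 2.83); the
asynchronous multi-origin population is flat and its reported "origin" is
just the location of the largest noise excursion, correctly labelled
`flat_multi_origin`.

The other examples cover skew profiling (`01`), flow-cytometry ploidy
(`03`) and the combined per-genome report with strategy classification
(`04`). A thin CLI mirrors the stages:

```sh
repliskew simulate --mode multifork --fork-intensity 1.5 --seed 1 --out-prefix demo
repliskew skew --fasta demo.fasta --gff demo.gff3 --mode both
repliskew mfa --exp demo.exp.bedgraph --stat demo.stat.bedgraph --genome-length 3000000
repliskew ploidy --sample s.csv --reference r.csv --ref-genome 2700000 --target-genome 4100000
repliskew report --config config.json --out-dir out/
```

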