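# Methods notes

This note records the models, the parameter choices that matter, and what
the synthetic benchmarks do and do not demonstrate.

## Coordinates and formats

All coordinates are 0-based half-open internally. methratio-style call
tables and GFF3 (1-based inclusive on disk) are shifted on read; BED passes
through unchanged. Cytosine contexts are read 5′→3′ on the strand carrying
the cytosine; a context window that runs off the chromosome or contains N
yields context `none` and the cytosine is excluded downstream.

## DMR caller

- **Windowing.** "200-bp windows with a 50-bp overlap" is implemented as
  step = 150 bp from position 0; windows extending past the chromosome end
  are dropped. The alternative reading (step 50) is available through
  `DMRCallerParams(window_overlap=150)`.
- **Pairing unit.** The Wilcoxon signed-rank test is applied to paired
  per-cytosine methylation ratios at positions covered (≥ `min_coverage`)
  in both samples. Methods that pool strands or aggregate counts first are
  defensible alternatives; per-cytosine pairing keeps the test's n equal to
  the number of informative sites.
- **Window level.** Count-weighted (Σ methylated / Σ total) by default;
  mean-of-ratios is available (`weighted_level=False`). Count weighting
  makes deeply covered cytosines count proportionally and is what
  methratio-style ratios aggregate to.
- **Filters.** `min_sites = 4` matched cytosines per window and
  `min_coverage = 4` reads per cytosine are this package's defaults; they
  stand in for an unspecified upstream filtering step and are exposed as
  parameters. Raw p < 0.05 is used — no multiple-testing correction — to
  match the published procedure; a BH option exists in `stats`.
- **Thresholds are inclusive** (|Δ| ≥ threshold), with a 10⁻¹² guard so a
  difference constructed to sit exactly on a threshold is never lost to
  float round-off.
- **Joining.** Retained windows of equal context and direction that overlap
  or abut are merged; the merged level is recalculated from raw counts over
  the merged extent. Merged regions are *not* re-required to pass the
  Δ threshold, and a single retained window is a valid DMR.
- **Performance.** The significance test is evaluated only for windows that
  already pass the site-count and Δ filters; the retained set is provably
  identical to testing every window. A 5-Mb genome at 20× coverage
  (≈ 2.5 M cytosines per sample) is called in well under a minute.

## Statistical machinery

- Wilcoxon signed-rank: zero differences dropped; exact null by dynamic
  programming over (doubled, so tie-midranks stay integral) ranks for
  n ≤ 25; otherwise normal approximation with tie and continuity
  corrections. Two-sided p = 2 × min(lower, upper tail), capped at 1.
- Mann-Whitney U: exact by enumeration for n₁+n₂ ≤ 12 without ties,
  otherwise the corrected normal approximation. Degenerate inputs (zero
  variance) return p = 1.
- Representation factor: R = x/(n₁n₂/N) with the hypergeometric upper tail;
  the lower tail is also reported when R < 1. The universe N must be chosen
  by the caller; the default helper uses genome length in 200-bp slots
  (`default_universe`), the window size of the DMR analysis. N is echoed in
  every overlap report because R and p are meaningless without it. When the
  observed overlap count exceeds min(n₁, n₂) — possible because the 50%
  rule is asymmetric — the hypergeometric count is clamped to the model's
  support; the raw count and percentage are unaffected.
- BH adjustment is the plain step-up procedure, cross-checked against
  statsmodels in the test suite.

## Photolesion-enrichment caller

A deliberately transparent stand-in for a model-based peak caller: binned
counts, library-size scaling, Poisson upper tail at λ = scaled input + 1,
BH across all bins, fold ≥ 2 and q ≤ 0.05, merge across ≤ 200-bp gaps,
re-scoring of merged regions on summed counts. Because the observed input
bin count is treated as the known rate, the test needs adequate input
depth: below roughly 30 input reads per bin, downward sampling noise in
the input inflates apparent fold changes and occasional false bins appear.
The synthetic study therefore sequences the input at twice the IP depth
(400k vs 200k reads on 1 Mb), which is also ordinary experimental
practice. CPD and 6,4-PP IPs are processed independently;
`union_regions` pools their calls into one photolesion set.

## Overlap, spreading, corrected overlap

The 50% rule is applied to the query's own length (bedtools `-f`), so the
relation is intentionally asymmetric; a reciprocal mode is a flag away.
For the corrected overlap, each damaged region is widened by the mean 5′/3′
spread, the intersection is computed against the widened interval, but the
50% denominator stays the *original* region length. With the denominator
on the widened length, a DMR lying wholly inside a damaged region could
fall below 50% after widening and the "corrected" count could drop below
the strict count — contradicting both the monotonicity property and the
meaning of a correction that only credits additional spread. DMR-to-damage
matching for the spreading measurement takes the largest overlap, leftmost
on ties; 5′/3′ are plus-strand conventions since the region sets are
unstranded.

## Synthetic-data generator

Deterministic under a seed; sub-generators draw from independent streams
keyed by (seed, module), so any data type regenerates in isolation.

- **Genome.** I.i.d. uniform A/C/G/T. One central pericentromere per
  chromosome (30% of length by default). Features: TE-dominated slots in
  the pericentromere (80%), PCG-dominated arms; exponential feature/gap
  lengths (2 kb / 1 kb means). Chromatin states 1–9 tile each chromosome
  in ≈ 5-kb segments, states 8–9 enriched in the pericentromere.
- **Methylomes.** Coverage ~ Poisson(20); methylated count ~ Binomial(cov,
  p); p set by compartment × context baselines (pericentromere CG/CHG/CHH
  0.85/0.65/0.10, arms 0.25/0.10/0.03 — Arabidopsis-like) and shifted by
  ±Δ inside planted DMRs in the treated sample. Defaults plant 100 CHH
  DMRs of 600 bp at Δ = +0.3, 90% pericentromeric. Zero-coverage cytosines
  are omitted, as in real call tables. A shift that leaves [0,1] is a
  configuration error, not a clamp.
- **Damage reads.** Input uniform; IP sampled per 200-bp bin with weight ∝
  (1 + (fold−1)·truth fraction) × (0.5 + di-pyrimidine density) ×
  chromatin-state weight. The density modulation is kept mild: real UV IP
  data show no strong di-pyrimidine bias between damaged and undamaged
  regions, the signal being dominated by the lesions themselves.
- **Small RNAs.** Three libraries (untreated, treated with boosted source
  share, POL IV-depleted treated); read lengths drawn from a 21/22/24 mix
  (0.25/0.15/0.60); source-interval reads are POL IV-dependent with
  probability 0.9 and removed from the depleted library. Library size
  10⁶ reads.
- **Images.** Elliptical nuclei (radius ≈ 30 px) at 0.45 intensity on a
  0.05 background with bright (1.0) circular spots sized to per-nucleus CO
  targets cycling 5–30%; optional Gaussian noise. Truth CO is computed from
  the drawn pixel masks, so discretisation is already accounted for.

What the generator does **not** model: replicate structure (one methylome
per condition, as in a pooled design), bisulfite conversion error, mapping
artefacts and multi-mapping biases, read-level sequence, fragment-length
effects in the IP, chromatin-dependent coverage, and optical blur beyond
additive Gaussian noise. Passing benchmarks therefore demonstrate the
correctness of the statistical machinery under its own assumptions, not
performance on real libraries.

## Chromocenter quantification

Otsu + connected components for nuclei (no watershed: touching nuclei
merge, a documented limitation; exclude by area/eccentricity or provide
masks). Spots are nucleus pixels above mean + k·sd with k = 2 by default.
On noise-free two-level nuclei the cut only separates spots from the body
when k < (1−f)/√(f(1−f)) for spot fraction f — k = 2 works for f < 0.20,
and validation across CO 5–30% uses k = 1 (the bound gives k < 1.53 at
f = 0.30). Real DAPI images have intensity spread that makes larger k
appropriate. All thresholds are relative, so measurements are invariant to
uniform intensity rescaling. Areas are reported in px; physical areas are
the caller's multiplication by their pixel size.

## Problem sizes used in the checks

Benchmarks run at desk scale, chosen to hold the statistical structure of
the full-genome analysis in miniature: 5 × 1 Mb chromosomes for DMR
parameter recovery, 1 Mb for damage-caller recovery, 100 kb for the
brute-force caller-equivalence oracle, 12-nucleus images. These sizes give
the callers hundreds of thousands of informative sites — adequate for the
binomial/Poisson error rates being verified.
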