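# Methods

## The analysis model

`earscan` quantifies *regional* enrichment of genome-wide fold-enrichment
signals (ChIP-seq fold enrichment over input, Spo11-oligo densities, S1-seq
coverage and the like) on the 16 nuclear chromosomes of *S. cerevisiae*.  The
coordinate frame is a `GenomeLayout` (chromosome lengths, centromere
midpoints, the rDNA interval on chrXII at 451,000–471,000); all genomic
intervals are 0-based half-open, so a span quoted as "20–110 kb from the
telomere" is `[20000, 110000)` measured from the assembly end.  Mitochondrial
and plasmid sequences are excluded from layouts by construction, and no
sequence-level information (FASTA, telomeric-repeat annotation, liftover) is
used: the analyses are relative to whatever assembly produced the input
track.

Signals are piecewise-constant per-base tracks.  Because the signal is
piecewise constant, its cumulative integral is piecewise linear, and every
statistic in the package — regional means, window means on circularized
chromosomes, fractional-boundary bin means — is an exact linear-interpolation
query on that integral, not an approximation.  Tracks are normalized to a
genome-wide, length-weighted mean of 1, so a regional mean of 1.5 reads
directly as 1.5-fold over genome average.  Positions not covered by a
bedGraph record are filled with 0 (sparse pileups omit zero-coverage runs).

Four landmark region classes are constructed per layout:

| class | definition | count (yeast) |
|---|---|---|
| EAR | `[20 kb, 110 kb)` from each chromosome end | 32 |
| interstitial | `[110 kb, L − 110 kb)` per chromosome | 16 |
| centromere window | width *w* centered on the centromere midpoint (2–50 kb) | 16 |
| rDNA flank | 100 kb on either side of the rDNA interval | 2 |

EARs, the two 0–20 kb terminal caps and the interstitial region tile each
chromosome exactly; the test suite checks this by width bookkeeping.
Chromosomes too short for a definition simply contribute no region and are
recorded in the region set's provenance (e.g. chrI, at 230,218 bp, has no
interior region left after 120-kb terminal exclusions).

## Regional statistics

Per-chromosome regional means are length-weighted; a chromosome's EAR value
averages its left and right domains (equal widths make this identical to
pooling base pairs).  The EAR-vs-interstitial comparison is a two-sided
two-sample Mann–Whitney–Wilcoxon test on the 16-vs-16 per-chromosome means:
exact null when both groups have n ≤ 20 and no ties, normal approximation
with continuity correction otherwise (ties by midranks).  The test is
unpaired by default; a paired signed-rank variant is exposed because the
pairing convention for by-chromosome comparisons is a legitimate judgment
call, but unpaired matches the way the group sizes are usually reported.
Multi-group comparisons (region × timepoint cells) use one-way ANOVA with
post-hoc Tukey HSD over all pairs.

The chromosome-size-bias regression fits ordinary least squares of
log2(per-chromosome mean enrichment) on log2(chromosome length), one point
per chromosome; slope, intercept, R² and the slope's t-test P (n − 2 df) are
reported.  "Mean enrichment per kb" is treated as presentational scaling of
the per-bp mean — it shifts the intercept, never the slope or R².  For two
samples, a joint model with a sample indicator and a sample × log2(length)
interaction is fitted; the interaction coefficient's P tests whether the two
slopes differ.  On noise-free input the residual variance is zero and the
interaction t-statistic is 0/0; the degenerate case is resolved to P = 1
when the coefficient is numerically zero and P = 0 otherwise.  The
EAR-excluded variant averages `[110 kb, L − 110 kb)` per chromosome and
reports the sample (n − 1) standard deviation of the means of 10 equal-width
bins as its dispersion; the n − 1 convention is conventional error-bar
practice and is a choice, not a given.

Hotspot tables (interval + signal, e.g. Spo11-oligo counts per hotspot) are
first filtered against exclusion regions — any overlap with the rDNA
interval removes the hotspot — then normalized to the global mean signal per
hotspot.  Class membership is decided by hotspot midpoint: hotspots
(~500 bp) are far smaller than the 90-kb regions, and midpoint assignment
avoids double counting.

## The circularized-chromosome bootstrap

The null distribution for a regional mean is built by dropping windows,
matched in width and number to the query, at uniform random integer starts
on each chromosome treated as a circle (windows running past the end wrap
to the start, so all L starts are equally likely).  Schemes:

* **ear** — two independent ("unlinked") 90-kb windows per chromosome,
  32 per replicate, matching the 32 EAR domains;
* **centromere** — one window per chromosome, width equal to the query
  window (2–50 kb);
* **rdna** — two 100-kb windows per genome, chromosome chosen with
  probability proportional to its eligible length after excluding the
  120-kb terminal zone at every chromosome end; windows intersecting an
  exclusion are redrawn (rejection sampling keeps windows contiguous in
  genome coordinates; 10,000 rejections per window before erroring).

The replicate statistic is the unweighted mean of the window means divided
by the track's genome mean; the observed statistic is the same functional
over the query regions.  The default replicate count is 5000; the null
calibration study uses 2000.  The 95% CI is the 2.5th–97.5th percentile of
the replicate distribution (linear interpolation between order statistics),
and the call is `above_CI` / `below_CI` / `within_CI`.  The empirical
percentile of the observed value uses the mid-rank convention
(100 × (#below + ½·#equal) / n).

Randomness: one root seed; per-replicate generators are seeded from a
prefix-stable stream of the root seed (`SeedSequence.generate_state`), so
raising the replicate count extends the replicate list without reshuffling
earlier replicates, and results are bitwise reproducible.

### Known conservatism of the scheme

The EAR scheme's two windows per chromosome are drawn independently and may
overlap each other, whereas the 32 observed EAR domains are disjoint; and
replicate windows that land on the EARs themselves (≈24% of the genome)
couple the per-track null's upper percentile to the observed value.  Both
effects make the replicate distribution over-dispersed relative to the
observed statistic: measured on no-effect synthetic genomes, the replicate
standard deviation is ≈1.24× the observed one, and the `above_CI` call
fires for ≈1% of null genomes rather than the nominal 2.5% (the acceptance
script recomputes this rate as `null_above_ci_rate_pct`).  The scheme is
therefore slightly conservative — an `above_CI` call is, if anything,
understated — and this property is scale-invariant, inherent to the
sampling design rather than to any particular genome size.

## Spike-in normalization

With a fraction *f* of spike-in cells mixed into each sample before
immunoprecipitation, the normalization factor is the input-corrected ChIP
ratio

    factor = (chip_target / chip_spike) / (input_target / input_spike),

the ChIP target-to-spike read ratio divided by the mixing ratio actually
measured in the input library.  A sample's level relative to a reference is
the ratio of factors; a relative level of 0.68 is reported as a 32%
reduction.  Replicate factors are averaged (not read-pooled).  Multiplying
mean-1-normalized regional means by the relative level puts samples on a
common absolute scale anchored to the reference.  The uncorrected ChIP-only
ratio is available for sensitivity checks.  The module consumes
unique-mapping read counts to the two genomes; it does not align reads.

## The synthetic generator

`make_track` emulates the statistical structure the analyses assume:
baseline 1 per bin; a multiplicative EAR factor (flat by default, optionally
decaying linearly from the fold at 20 kb to 1 at 110 kb, mirroring observed
distance-from-telomere profiles); optional centromere-window and rDNA-flank
factors; a per-chromosome size-bias factor `(L / L_median) ** beta`
(anchored at the median length so beta does not shift the genome mean
systematically); independent mean-1 log-normal noise per bin,
`exp(N(−sd²/2, sd))`; and a final normalization to genome mean exactly 1.
Segment edges are split at region boundaries so injected folds are exact:
the noise-free EAR/interstitial mean ratio equals the configured fold to
machine precision, and an injected beta is recovered by the size-bias fit
to 1e-9.

Defaults are the study conditions: EAR fold 1.5 (the approximate scale of
late-prophase axis-factor enrichment), noise_sd 0.3 with 100-bp bins
(positive, right-skewed values resembling fold-enrichment tracks — the
choice is documented, not claimed to match any particular dataset), 3600
hotspots of 500 bp with mean-1 gamma signal dispersion (CV 1.0), 15%
spike-in fraction and 10⁶-read libraries.  Hotspot midpoints are placed
uniformly, never inside the rDNA; signals are the local track value times
the dispersion factor.  Spike-in counts are binomial draws at the configured
depth, with the ChIP target proportion scaled by the sample's true relative
occupancy.

What the generator does **not** emulate: spatial autocorrelation beyond the
bin scale (real ChIP fragments correlate over ~0.5–1 kb), peak/hotspot
shape, replication-timing or transcription covariates, mappability gaps,
and read-level sampling noise.  Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise model,
not robustness to every artifact of real sequencing data.

## Problem sizes and numerical choices

The calibration and recovery studies are sized to run comfortably on a
single CPU: the null-calibration study uses 400 no-effect genomes on a
1/10-scale layout with 10-bp noise bins (so each 9-kb bootstrap window
averages 900 independent noise elements, exactly as a 90-kb window does at
full scale with 100-bp bins — the window/chromosome-length ratios that
govern bootstrap behavior are scale-invariant) and 2000 replicates per
genome; enumeration equivalence uses 50,000 replicates against the exact
1000-start distribution; effect-recovery studies use 100 genomes per
effect at full scale.  Tolerances: normalization to mean 1 within 1e-9;
track totals conserved by binning within 1e-9; exact rank-sum p-values
verified against brute-force enumeration for all group sizes ≤ 6.

## Limitations

* The bootstrap null is conditional on the observed track; with strong
  genuine regional structure the null inherits some of that structure
  (replicate windows sample the enriched regions too), which is the
  intended behavior of the published design but means CI exceedance is a
  conservative, not exact, 2.5% test (see above).
* Per-chromosome rank tests treat chromosomes as exchangeable units;
  chromosome-level covariates (e.g. rDNA on chrXII) are not modeled.
* Hotspot aggregation assigns by midpoint only; hotspots comparable in
  size to the regions would need overlap-fraction weighting.
* No analytic null, no block bootstrap of signal values, and no plotting
  beyond tabular export of replicate vectors for violin rendering.
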