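# earscan

Regional enrichment analysis of meiotic ChIP-seq-style signals on the budding
yeast genome: chromosome **end-adjacent regions (EARs)**, circularized-
chromosome bootstrap nulls, spike-in rescaling of total levels, and
chromosome-size-bias regression.

## The problem

During meiotic prophase, programmed DNA double-strand breaks (DSBs) are
progressively down-regulated as homologs synapse — except in privileged
~90-kb domains 20–110 kb from every telomere (EARs), which retain the
DSB-promoting axis protein Hop1 and keep breaking late into prophase.
Because EARs have roughly constant size, they occupy a much larger *fraction*
of short chromosomes, which helps explain the classically elevated
recombination density of short chromosomes.  Testing these ideas on
genome-wide fold-enrichment tracks (γ-H2A, Hop1, Red1, Zip1 ChIP-seq;
Spo11-oligo and S1-seq densities) requires a small, reusable set of regional
statistics:

* **Region construction** — EARs (`[20 kb, 110 kb)` from each end; 32
  domains), interstitial territory (>110 kb from either end; 16 domains),
  centromere windows (2–50 kb), and 100-kb rDNA flanks, on any genome layout
  (0-based, half-open coordinates).
* **Regional means and tests** — length-weighted per-chromosome means on
  mean-1-normalized tracks; two-sided Mann–Whitney–Wilcoxon on the 16-vs-16
  chromosome means (exact for small tie-free samples); one-way ANOVA +
  Tukey HSD for region × timepoint panels.
* **Circular bootstrap** — the null for "is the EAR mean high?" is built by
  dropping windows matched in size and number to the query at uniform random
  positions on each circularized chromosome (5000 replicates), and asking
  whether the observed mean exceeds the two-ended 95% CI.
* **Spike-in rescaling** — input-corrected target/spike read ratios convert
  mean-1 tracks into absolute levels relative to a reference sample
  (relative level 0.68 ⇒ "32% reduction").
* **Size-bias regression** — OLS of log2(per-chromosome mean) on
  log2(chromosome length), with a two-sample interaction test for slope
  differences and an EAR-excluded variant with 10-bin dispersion.
* **Synthetic data** — a seeded generator producing tracks, hotspot tables
  and spike-in counts with configurable EAR folds, gradients, size-bias
  slopes and multiplicative noise, so every stage is testable and
  calibratable without sequencing data.

See `docs/methods.md` for the statistical details and the design choices.

## Worked example

Simulate a late-prophase-like genome (1.5-fold EAR enrichment, lognormal
noise), then run the full regional analysis:

```python
import earscan as es

layout = es.load_layout("yeast")
cfg    = es.SyntheticConfig(layout=layout, ear_fold=1.5, noise_sd=0.3, seed=42)
track  = es.make_track(cfg)                      # genome mean exactly 1

ears  = es.define_ears(layout)                   # 32 domains
inter = es.define_interstitial(layout)           # 16 domains
em = es.per_chrom_region_means(track, ears, "EAR")
im = es.per_chrom_region_means(track, inter, "interstitial")
test = es.ear_vs_interstitial_test(em, im)

res = es.run_bootstrap(track, es.ear_spec(n_reps=5000, seed=7), ears)
fit = es.size_bias_fit({"late": track}, layout)
```

Output (printed by the snippet above with small `print` formatting):

```
mean EAR enrichment          1.336
mean interstitial enrichment 0.894
MWW p-value (16 vs 16)       3.33e-09
bootstrap median / 95% CI    1.031 / [0.987, 1.079]
observed EAR statistic       1.336  -> above_CI
size-bias slope (log2-log2)  -0.140  R^2 0.953  P 1.15e-10
```

Reading it: EARs run 1.34-fold over genome average while interstitial
territory sits at 0.89 (their ratio recovers the injected 1.5-fold), the
rank-sum test on per-chromosome means is maximally significant, the observed
EAR statistic lies far above the bootstrap 95% CI, and — although no
per-chromosome bias was injected — the fixed-size EARs alone induce a
negative size-bias slope (short chromosomes over-enriched), which is the
mechanism of interest.

The same analyses are scriptable from the shell:

```sh
earscan simulate --seed 42 --out track.bedgraph
earscan regions  --out regions/
earscan enrich    --track track.bedgraph --out enrich.tsv
earscan bootstrap --track track.bedgraph --scheme ear --reps 5000 --seed 7 --out boot.tsv
earscan sizebias  --track track.bedgraph --out sizebias.tsv
```

(`earscan run --config cfg.yaml --out out/` drives several stages from one
YAML file and writes a JSON manifest.)

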