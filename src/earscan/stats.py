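"""Regional comparison statistics.

Implements the per-chromosome summaries and hypothesis tests used to compare
chromosome end-adjacent regions (EARs) against interstitial territory:

* per-chromosome length-weighted regional means (one value per chromosome and
  region class; a chromosome's EAR value averages its left and right domains);
* the two-sample Mann-Whitney-Wilcoxon test on those 16-vs-16 chromosome
  means (exact null for small tie-free samples, normal approximation with
  continuity correction otherwise);
* one-way ANOVA with post-hoc Tukey HSD for multi-group (e.g. region x
  timepoint) comparisons;
* the chromosome-size-bias regression: OLS of log2(per-chromosome mean
  enrichment) on log2(chromosome length), with a two-sample interaction model
  testing whether two samples' slopes differ;
* the EAR-excluded per-chromosome means with the dispersion of 10 equal-width
  bins, used to ask how much of the size bias survives removal of the EARs;
* hotspot-level aggregation of interval-count tables (e.g. Spo11-oligo counts
  per hotspot), normalized to the genome-average hotspot signal, with
  exclusion filtering (rDNA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import GenomeLayout, RegionSet, define_interstitial
from .tracks import SignalTrack

__all__ = [
    "TestResult", "SizeBiasFit", "HotspotClassSignal",
    "per_chrom_region_means", "ear_vs_interstitial_test", "group_anova_tukey",
    "size_bias_fit", "ear_excluded_chrom_means", "hotspot_regional_signal",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]
    sidedness: str = "two-sided"
    higher_median: str | None = None

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)


@dataclass
class SizeBiasFit:
    """Per-sample log2-log2 regression of chromosome mean on chromosome length."""

    samples: tuple[str, ...]
    slope: dict[str, float]
    intercept: dict[str, float]
    r_squared: dict[str, float]
    slope_p: dict[str, float]
    n_chrom: int
    interaction_p: float | None = None  # slope-difference P for two samples

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": list(self.samples),
            "slope": [self.slope[s] for s in self.samples],
            "intercept": [self.intercept[s] for s in self.samples],
            "r_squared": [self.r_squared[s] for s in self.samples],
            "slope_p": [self.slope_p[s] for s in self.samples],
        })


def per_chrom_region_means(track: SignalTrack, regions: RegionSet,
                           class_label: str = "") -> pd.Series:
    """Length-weighted mean signal per chromosome over that chromosome's
    regions of the class.  Chromosomes without a region are absent."""
    if len(regions) == 0:
        raise ValueError("empty region set")
    out: dict[str, float] = {}
    for chrom in track.layout.chrom_names:
        sub = regions.on_chrom(chrom)
        if not sub:
            continue
        integ = sum(float(track.integral(chrom, r.start, r.end)) for r in sub)
        width = sum(r.width for r in sub)
        out[chrom] = integ / width
    s = pd.Series(out, name=class_label or regions.provenance.get("constructor", "mean"))
    s.index.name = "chrom"
    return s


def ear_vs_interstitial_test(ear_means: pd.Series, interstitial_means: pd.Series,
                             paired: bool = False) -> TestResult:
    """Rank test of per-chromosome EAR means against interstitial means.

    Unpaired (two-sample Mann-Whitney-Wilcoxon) by default; ``paired=True``
    runs the Wilcoxon signed-rank test on chromosomes present in both series.
    Exact null distribution when both groups have n <= 20 and there are no
    ties; otherwise the normal approximation with continuity correction.
    """
    x = np.asarray(ear_means, dtype=float)
    y = np.asarray(interstitial_means, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 chromosomes per class")
    higher = "EAR" if np.median(x) >= np.median(y) else "interstitial"
    if paired:
        common = ear_means.index.intersection(interstitial_means.index)
        res = sps.wilcoxon(ear_means[common], interstitial_means[common])
        return TestResult(float(res.statistic), float(res.pvalue),
                          "wilcoxon-signed-rank", ("EAR", "interstitial"),
                          (len(common), len(common)), higher_median=higher)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(x) <= 20 and len(y) <= 20) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=(method == "asymptotic"))
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"mann-whitney-wilcoxon ({method})", ("EAR", "interstitial"),
                      (len(x), len(y)), higher_median=higher)


def group_anova_tukey(groups: dict[str, np.ndarray]) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA across labeled groups, plus all-pairs Tukey HSD.

    Returns the ANOVA result and one :class:`TestResult` per group pair with
    the Tukey-adjusted p-value.
    """
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs n >= 2")
    f, p = sps.f_oneway(*samples)
    anova = TestResult(float(f), float(p), "one-way-anova", tuple(labels),
                       tuple(len(s) for s in samples))
    hsd = sps.tukey_hsd(*samples)
    pairs: list[TestResult] = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pairs.append(TestResult(
                float(hsd.statistic[i, j]), float(hsd.pvalue[i, j]), "tukey-hsd",
                (labels[i], labels[j]), (len(samples[i]), len(samples[j]))))
    return anova, pairs


def _whole_chrom_means(track: SignalTrack) -> pd.Series:
    out = {c: float(track.mean_over(c, 0, track.layout.length_of(c)))
           for c in track.layout.chrom_names}
    return pd.Series(out, name="whole-chromosome")


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, R^2 and slope P (t-test, n-2 df) of y on x."""
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2), float(res.pvalue)


def size_bias_fit(tracks: dict[str, SignalTrack] | SignalTrack,
                  layout: GenomeLayout | None = None,
                  chrom_means: dict[str, pd.Series] | None = None) -> SizeBiasFit:
    """Chromosome-size-bias regression on log2 scale.

    For each sample, the per-chromosome whole-chromosome mean enrichment is
    regressed (OLS) on chromosome length, both log2-transformed; a negative
    slope means short chromosomes carry disproportionately high signal.  With
    exactly two samples the joint model ``log2(mean) ~ log2(L) * sample`` is
    also fitted and the interaction (slope-difference) P reported.

    ``chrom_means`` may supply precomputed per-chromosome means keyed by
    sample, bypassing the tracks.
    """
    import statsmodels.api as sm

    if chrom_means is None:
        if isinstance(tracks, SignalTrack):
            tracks = {"sample": tracks}
        chrom_means = {name: _whole_chrom_means(t) for name, t in tracks.items()}
        layout = layout or next(iter(tracks.values())).layout
    if layout is None:
        raise ValueError("layout required when passing precomputed chrom_means")

    lengths = pd.Series(layout.lengths())
    samples = tuple(chrom_means)
    slope, intercept, r2, slope_p = {}, {}, {}, {}
    frames = []
    for name in samples:
        means = chrom_means[name]
        if (means <= 0).any():
            raise ValueError(f"sample {name!r} has a non-positive chromosome mean; cannot log")
        x = np.log2(lengths[means.index].to_numpy(dtype=float))
        y = np.log2(means.to_numpy(dtype=float))
        slope[name], intercept[name], r2[name], slope_p[name] = _ols_line(x, y)
        frames.append(pd.DataFrame({"x": x, "y": y, "sample": name}))

    interaction_p = None
    if len(samples) == 2:
        df = pd.concat(frames, ignore_index=True)
        ind = (df["sample"] == samples[1]).astype(float).to_numpy()
        X = sm.add_constant(np.column_stack([df["x"], ind, df["x"] * ind]))
        fit = sm.OLS(df["y"].to_numpy(), X).fit()
        coef, p = fit.params[3], fit.pvalues[3]
        if np.isnan(p):  # zero residual variance (noise-free input)
            p = 1.0 if abs(coef) < 1e-10 else 0.0
        interaction_p = float(p)

    return SizeBiasFit(samples=samples, slope=slope, intercept=intercept,
                       r_squared=r2, slope_p=slope_p,
                       n_chrom=len(next(iter(chrom_means.values()))),
                       interaction_p=interaction_p)


def ear_excluded_chrom_means(track: SignalTrack, layout: GenomeLayout | None = None,
                             margin: int = 110000, n_bins: int = 10) -> pd.DataFrame:
    """Per-chromosome mean over ``[margin, L - margin)`` with a 10-bin SD.

    The dispersion column is the sample (n-1) standard deviation of the means
    of ``n_bins`` equal-width bins spanning the EAR-excluded interval; it is
    the error bar of the telomere-distal size-bias analysis.  Chromosomes with
    ``L <= 2 * margin`` are absent from the table.
    """
    layout = layout or track.layout
    rows = {}
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
        if length <= 2 * margin:
            continue
        lo, hi = float(margin), float(length - margin)
        edges = np.linspace(lo, hi, n_bins + 1)
        bin_means = np.asarray(track.mean_over(chrom, edges[:-1], edges[1:]))
        rows[chrom] = {"mean": float(track.mean_over(chrom, lo, hi)),
                       "sd": float(np.std(bin_means, ddof=1))}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "chrom"
    return df


@dataclass
class HotspotClassSignal:
    """Mean normalized hotspot signal per region class, pooled and per chromosome."""

    pooled: dict[str, float]
    per_chrom: pd.DataFrame  # index chrom, one column per class
    n_hotspots: dict[str, int]
    n_excluded: int


def hotspot_regional_signal(hotspots: pd.DataFrame,
                            classes: dict[str, RegionSet],
                            exclusions: RegionSet | None = None) -> HotspotClassSignal:
    """Aggregate hotspot signal (e.g. Spo11-oligo counts) by region class.

    ``hotspots`` is a BED-like frame with columns ``chrom, start, end, signal``.
    Hotspots overlapping any exclusion region (e.g. the rDNA interval) are
    removed first; remaining signals are normalized to their global mean, so a
    class mean of 1 equals genome-average hotspot signal.  Class membership is
    by hotspot midpoint.
    """
    df = hotspots.copy()
    required = {"chrom", "start", "end", "signal"}
    if not required.issubset(df.columns):
        raise ValueError(f"hotspot table must have columns {sorted(required)}")

    n0 = len(df)
    if exclusions is not None and len(exclusions) > 0:
        keep = np.ones(len(df), dtype=bool)
        for i, row in enumerate(df.itertuples(index=False)):
            for r in exclusions.on_chrom(row.chrom):
                if row.start < r.end and row.end > r.start:
                    keep[i] = False
                    break
        df = df[keep]
    if len(df) == 0:
        raise ValueError("no hotspots remain after exclusion filtering")

    global_mean = df["signal"].mean()
    if global_mean <= 0:
        raise ValueError("global mean hotspot signal is non-positive")
    df = df.assign(norm=df["signal"] / global_mean,
                   mid=(df["start"] + df["end"]) // 2)

    pooled: dict[str, float] = {}
    n_hot: dict[str, int] = {}
    per_chrom_cols: dict[str, pd.Series] = {}
    for label, regions in classes.items():
        in_class = np.zeros(len(df), dtype=bool)
        for i, row in enumerate(df.itertuples(index=False)):
            for r in regions.on_chrom(row.chrom):
                if r.start <= row.mid < r.end:
                    in_class[i] = True
                    break
        sub = df[in_class]
        n_hot[label] = len(sub)
        pooled[label] = float(sub["norm"].mean()) if len(sub) else float("nan")
        per_chrom_cols[label] = sub.groupby("chrom")["norm"].mean()
    per_chrom = pd.DataFrame(per_chrom_cols)
    per_chrom.index.name = "chrom"
    return HotspotClassSignal(pooled=pooled, per_chrom=per_chrom,
                              n_hotspots=n_hot, n_excluded=n0 - len(df))
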