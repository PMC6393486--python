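"""Circularized-chromosome bootstrap null distributions.

The null model for a regional enrichment statistic is built by resampling:
each chromosome is treated as a circle, and windows matched in width and
number to the experimental query are dropped at uniform random start
positions (windows running past the end wrap around to the start, so every
start is equally likely).  The replicate statistic is the unweighted mean of
the sampled windows' means divided by the track's genome mean; repeating
5000 times yields a distribution whose median and 2.5th/97.5th percentiles
(the two-ended 95% CI) calibrate the observed regional mean.

Three sampling schemes mirror the region classes:

* ``ear``        - two unlinked windows (default 90 kb) per chromosome;
* ``centromere`` - a single window per chromosome (width = query width);
* ``rdna``       - two windows per *genome* (default 100 kb), chromosome
  chosen with probability proportional to eligible length, with windows
  redrawn if they intersect an exclusion set (conventionally the 120-kb
  terminal zones of every chromosome).

Replicate random streams are derived per replicate from the root seed, so
increasing ``n_reps`` extends the replicate list without reshuffling earlier
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeLayout, Region, RegionSet, merged_intervals
from .tracks import SignalTrack

__all__ = ["BootstrapSpec", "BootstrapResult", "sample_windows", "run_bootstrap",
           "empirical_position", "ear_spec", "centromere_spec", "rdna_spec"]

_MAX_REJECT = 10000


@dataclass
class BootstrapSpec:
    """Parameters of one bootstrap scheme."""

    scheme: str  # "ear" | "centromere" | "rdna" | "custom"
    window_width: int
    windows_per_unit: int  # per chromosome (ear/centromere/custom), per genome (rdna)
    n_reps: int = 5000
    exclusions: RegionSet | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_width < 1:
            raise ValueError("window_width must be >= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.scheme not in ("ear", "centromere", "rdna", "custom"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


def ear_spec(n_reps: int = 5000, seed: int = 0, window_width: int = 90000) -> BootstrapSpec:
    """Two unlinked windows per chromosome (EAR-matched)."""
    return BootstrapSpec("ear", window_width, 2, n_reps=n_reps, seed=seed)


def centromere_spec(window_width: int, n_reps: int = 5000, seed: int = 0) -> BootstrapSpec:
    """One window per chromosome, width matched to the centromere query."""
    return BootstrapSpec("centromere", window_width, 1, n_reps=n_reps, seed=seed)


def rdna_spec(layout: GenomeLayout, n_reps: int = 5000, seed: int = 0,
              window_width: int = 100000, terminal_exclusion: int = 120000) -> BootstrapSpec:
    """Two windows per genome with terminal zones excluded.

    The default exclusion removes the 120-kb zone at both ends of every
    chromosome from the territory eligible for sampling.
    """
    regions = []
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
        regions.append(Region(chrom, 0, min(terminal_exclusion, length), "excl-left"))
        if length > terminal_exclusion:
            regions.append(Region(chrom, length - terminal_exclusion, length, "excl-right"))
    excl = RegionSet(regions, provenance={"constructor": "terminal_exclusion",
                                          "margin": terminal_exclusion})
    return BootstrapSpec("rdna", window_width, 2, n_reps=n_reps, seed=seed, exclusions=excl)


@dataclass
class BootstrapResult:
    rep_statistics: np.ndarray
    observed: float
    median: float
    ci_low: float
    ci_high: float
    spec: BootstrapSpec

    @property
    def observed_above_ci(self) -> bool:
        return self.observed > self.ci_high

    @property
    def observed_below_ci(self) -> bool:
        return self.observed < self.ci_low

    @property
    def empirical_percentile(self) -> float:
        reps = self.rep_statistics
        below = np.count_nonzero(reps < self.observed)
        equal = np.count_nonzero(reps == self.observed)
        return 100.0 * (below + 0.5 * equal) / len(reps)

    def summary_row(self) -> dict:
        pct, call = empirical_position(self)
        return {"scheme": self.spec.scheme, "n_reps": self.spec.n_reps,
                "observed": self.observed, "median": self.median,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "percentile": pct, "call": call}


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _rep_seeds(seed: int, n_reps: int) -> np.ndarray:
    """Per-replicate 64-bit seeds; a prefix-stable stream of the root seed."""
    return np.random.SeedSequence(seed).generate_state(n_reps, dtype=np.uint64)


def _circular_regions(chrom: str, start: int, width: int, length: int,
                      label: str) -> list[Region]:
    end = start + width
    if end <= length:
        return [Region(chrom, start, end, label)]
    return [Region(chrom, start, length, label), Region(chrom, 0, end - length, label)]


def _window_intersects(start: int, width: int, length: int, merged: np.ndarray) -> bool:
    pieces = [(start, min(start + width, length))]
    if start + width > length:
        pieces.append((0, start + width - length))
    for s, e in pieces:
        for ms, me in merged:
            if s < me and e > ms:
                return True
    return False


def sample_windows(layout: GenomeLayout, spec: BootstrapSpec,
                   rng: np.random.Generator) -> RegionSet:
    """Draw one replicate's windows as a :class:`RegionSet`.

    Wrapped windows are represented as two regions sharing a label.  For the
    per-chromosome schemes, draws are consumed chromosome-major then window
    index ("unlinked" independent windows).  For the genome-wide scheme, the
    chromosome of each window is drawn with probability proportional to its
    eligible (non-excluded) length and the window redrawn on any exclusion
    overlap (up to 10,000 rejections).
    """
    regions: list[Region] = []
    w = spec.window_width
    if spec.scheme in ("ear", "centromere", "custom"):
        for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
            if w > length:
                raise ValueError(f"window width {w} exceeds chromosome {chrom} length {length}")
            u = rng.random(spec.windows_per_unit)
            for j, start in enumerate((u * length).astype(np.int64)):
                regions.extend(_circular_regions(chrom, int(start), w, length, f"win{j}"))
    else:  # rdna: genome-wide draws with rejection on exclusions
        merged = merged_intervals(spec.exclusions) if spec.exclusions else {}
        eligible = np.array([
            length - int(np.sum(np.diff(merged[chrom], axis=1))) if chrom in merged else length
            for chrom, length in zip(layout.chrom_names, layout.chrom_lengths)], dtype=float)
        if np.all(eligible < w):
            raise ValueError("eligible territory narrower than window on every chromosome")
        probs = eligible / eligible.sum()
        for j in range(spec.windows_per_unit):
            for attempt in range(_MAX_REJECT + 1):
                ci = rng.choice(len(probs), p=probs)
                chrom = layout.chrom_names[ci]
                length = layout.chrom_lengths[ci]
                if w > length:
                    continue
                start = int(rng.random() * length)
                m = merged.get(chrom, np.empty((0, 2), dtype=np.int64))
                if not _window_intersects(start, w, length, m):
                    regions.extend(_circular_regions(chrom, start, w, length, f"win{j}"))
                    break
            else:
                raise RuntimeError("exceeded 10,000 rejections while sampling a window")
    return RegionSet(regions, provenance={"constructor": "sample_windows",
                                          "scheme": spec.scheme})


def _rep_statistics_vectorized(track: SignalTrack, spec: BootstrapSpec) -> np.ndarray:
    """Replicate statistics for the per-chromosome schemes, batched.

    Start positions follow exactly the per-replicate stream of
    :func:`sample_windows`; window means are then evaluated vectorized per
    chromosome from the track's cumulative integral.
    """
    layout = track.layout
    n_reps, k, w = spec.n_reps, spec.windows_per_unit, spec.window_width
    n_chrom = layout.n_chromosomes
    seeds = _rep_seeds(spec.seed, n_reps)
    u = np.empty((n_reps, n_chrom * k))
    for i, s in enumerate(seeds):
        u[i] = np.random.Generator(np.random.PCG64(int(s))).random(n_chrom * k)
    means = np.empty_like(u)
    for ci, (chrom, length) in enumerate(zip(layout.chrom_names, layout.chrom_lengths)):
        if w > length:
            raise ValueError(f"window width {w} exceeds chromosome {chrom} length {length}")
        cols = slice(ci * k, (ci + 1) * k)
        starts = (u[:, cols] * length).astype(np.int64).astype(float)
        means[:, cols] = track.circular_window_mean(chrom, starts.ravel(), w).reshape(-1, k)
    return means.mean(axis=1)


def _rep_statistics_rdna(track: SignalTrack, spec: BootstrapSpec) -> np.ndarray:
    layout = track.layout
    seeds = _rep_seeds(spec.seed, spec.n_reps)
    stats = np.empty(spec.n_reps)
    for i, s in enumerate(seeds):
        rng = np.random.Generator(np.random.PCG64(int(s)))
        windows = sample_windows(layout, spec, rng)
        # group wrapped pieces back into windows by (label, order)
        means = _regionset_window_means(track, windows, spec.window_width)
        stats[i] = means.mean()
    return stats


def _regionset_window_means(track: SignalTrack, regions: RegionSet, width: int) -> np.ndarray:
    """Means of equal-width windows, re-joining wrapped pieces by width."""
    means = []
    pending = None  # (chrom-integral so far, bp so far)
    for r in regions:
        integ = float(track.integral(r.chrom, r.start, r.end))
        if pending is None:
            if r.width == width:
                means.append(integ / width)
            else:
                pending = (integ, r.width)
        else:
            total_i, total_w = pending[0] + integ, pending[1] + r.width
            if total_w != width:
                raise ValueError("window pieces do not reassemble to window width")
            means.append(total_i / width)
            pending = None
    if pending is not None:
        raise ValueError("dangling wrapped window piece")
    return np.asarray(means)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_bootstrap(track: SignalTrack, spec: BootstrapSpec,
                  observed_regions: RegionSet) -> BootstrapResult:
    """Build the bootstrap null and locate the observed regional mean in it.

    The replicate statistic is the unweighted mean of the sampled windows'
    means divided by the track's genome mean; the observed statistic is the
    unweighted mean of the observed regions' means on the same scale.  The CI
    is the 2.5th-97.5th percentile interval (linear interpolation).
    """
    if len(observed_regions) == 0:
        raise ValueError("observed_regions is empty")
    gm = track.genome_mean
    if gm <= 0:
        raise ValueError("track genome mean must be positive")
    if spec.scheme == "rdna":
        reps = _rep_statistics_rdna(track, spec) / gm
    else:
        reps = _rep_statistics_vectorized(track, spec) / gm
    obs_means = np.array([track.mean_over(r.chrom, r.start, r.end)
                          for r in observed_regions], dtype=float)
    observed = float(obs_means.mean() / gm)
    lo, med, hi = np.percentile(reps, [2.5, 50.0, 97.5])
    return BootstrapResult(rep_statistics=reps, observed=observed,
                           median=float(med), ci_low=float(lo), ci_high=float(hi),
                           spec=spec)


def empirical_position(result: BootstrapResult) -> tuple[float, str]:
    """Percentile of the observed value in the replicate distribution and the
    CI call: ``above_CI`` / ``below_CI`` / ``within_CI``."""
    if result.observed_above_ci:
        call = "above_CI"
    elif result.observed_below_ci:
        call = "below_CI"
    else:
        call = "within_CI"
    return result.empirical_percentile, call
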