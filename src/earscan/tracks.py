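"""Genome-wide signal tracks: piecewise-constant fold-enrichment over a layout.

A :class:`SignalTrack` stores, per chromosome, a run-length encoding of the
signal: breakpoints ``bounds[0]=0 < ... < bounds[n]=L`` and one value per run.
Because the signal is piecewise constant, its cumulative integral is piecewise
linear in position, so every length-weighted mean over an arbitrary interval
is computed exactly by linear interpolation of the cumulative integral at the
interval ends.  All regional statistics in this package reduce to such
integral queries.

Tracks are conventionally normalized so the genome-wide, length-weighted mean
is 1; a regional mean of 1.5 then reads directly as 1.5-fold over genome
average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .genome import GenomeLayout, Region, RegionSet

__all__ = ["SignalTrack", "ProfileCurve", "read_bedgraph", "write_bedgraph",
           "normalize_global_mean", "region_mean", "bin_track", "distance_profile"]


@dataclass
class _ChromSignal:
    bounds: np.ndarray  # int64/float64, shape (n+1,), bounds[0]=0, bounds[-1]=L
    values: np.ndarray  # float64, shape (n,)
    _cum: np.ndarray | None = None

    @property
    def cum(self) -> np.ndarray:
        """Cumulative integral of the signal at each breakpoint."""
        if self._cum is None:
            widths = np.diff(self.bounds).astype(float)
            self._cum = np.concatenate(([0.0], np.cumsum(self.values * widths)))
        return self._cum

    def integral(self, a, b) -> np.ndarray:
        """Exact integral of the signal over [a, b) (vectorized)."""
        fa = np.interp(a, self.bounds, self.cum)
        fb = np.interp(b, self.bounds, self.cum)
        return fb - fa


@dataclass
class SignalTrack:
    """Piecewise-constant per-base signal covering every chromosome of a layout."""

    layout: GenomeLayout
    chroms: dict[str, _ChromSignal]

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_arrays(cls, layout: GenomeLayout,
                    segments: dict[str, tuple[np.ndarray, np.ndarray]]) -> "SignalTrack":
        """Build from per-chromosome ``(bounds, values)`` arrays.

        Chromosomes of the layout missing from ``segments`` are filled with a
        single zero-valued run.
        """
        chroms: dict[str, _ChromSignal] = {}
        for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
            if chrom in segments:
                bounds, values = segments[chrom]
                bounds = np.asarray(bounds, dtype=np.float64)
                values = np.asarray(values, dtype=np.float64)
                if bounds[0] != 0 or bounds[-1] != length or len(bounds) != len(values) + 1:
                    raise ValueError(f"segments do not tile chromosome {chrom}")
                if np.any(np.diff(bounds) <= 0):
                    raise ValueError(f"non-increasing breakpoints on {chrom}")
                chroms[chrom] = _ChromSignal(bounds, values)
            else:
                chroms[chrom] = _ChromSignal(
                    np.array([0.0, float(length)]), np.zeros(1))
        return cls(layout, chroms)

    @classmethod
    def constant(cls, layout: GenomeLayout, value: float = 1.0) -> "SignalTrack":
        return cls.from_arrays(layout, {
            c: (np.array([0.0, float(l)]), np.array([float(value)]))
            for c, l in zip(layout.chrom_names, layout.chrom_lengths)})

    # -- core queries ----------------------------------------------------

    @property
    def genome_mean(self) -> float:
        total = sum(cs.cum[-1] for cs in self.chroms.values())
        return float(total / self.layout.genome_size)

    def integral(self, chrom: str, a, b):
        return self.chroms[chrom].integral(a, b)

    def mean_over(self, chrom: str, a, b):
        """Length-weighted mean over [a, b) (vectorized over array endpoints)."""
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        return self.chroms[chrom].integral(a, b) / (b - a)

    def circular_window_mean(self, chrom: str, starts, width: int):
        """Mean over windows [s, s+width) on the circularized chromosome.

        Windows running past the chromosome end wrap around to its start.
        """
        cs = self.chroms[chrom]
        length = cs.bounds[-1]
        starts = np.asarray(starts, dtype=float)
        ends = starts + width
        main = cs.integral(starts, np.minimum(ends, length))
        wrapped = np.where(ends > length, cs.integral(0.0, np.maximum(ends - length, 0.0)), 0.0)
        return (main + wrapped) / width

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack(self.layout, {
            c: _ChromSignal(cs.bounds, cs.values * factor) for c, cs in self.chroms.items()})

    def values_equal(self, other: "SignalTrack", atol: float = 0.0) -> bool:
        for c, cs in self.chroms.items():
            ocs = other.chroms[c]
            if not (np.array_equal(cs.bounds, ocs.bounds)
                    and np.allclose(cs.values, ocs.values, atol=atol, rtol=0)):
                return False
        return True


@dataclass
class ProfileCurve:
    """Signal averaged in distance bins from an anchor (telomere or centromere)."""

    anchor: str
    bin_width: int
    bins: pd.DataFrame  # columns: distance_start, distance_end, mean, n_bp

    def to_tsv(self, path: str | Path) -> None:
        self.bins.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path, layout: GenomeLayout) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Positions not covered by any record are filled with 0 (sparse upstream
    pileups omit zero-coverage runs).  Overlapping records, unknown
    chromosomes and intervals past the chromosome end are errors.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    segments: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in layout.chrom_names:
            raise ValueError(f"bedGraph chromosome {chrom!r} not in layout")
        length = layout.length_of(chrom)
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        vals = sub["value"].to_numpy(dtype=np.float64)
        if ends[-1] > length:
            raise ValueError(f"bedGraph interval ends at {ends[-1]} beyond {chrom} length {length}")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping bedGraph records on {chrom}")
        # interleave zero-fill gaps
        bounds = [0.0]
        values: list[float] = []
        for s, e, v in zip(starts, ends, vals):
            if s > bounds[-1]:
                values.append(0.0)
                bounds.append(float(s))
            values.append(float(v))
            bounds.append(float(e))
        if bounds[-1] < length:
            values.append(0.0)
            bounds.append(float(length))
        segments[chrom] = (np.array(bounds), np.array(values))
    return SignalTrack.from_arrays(layout, segments)


def write_bedgraph(track: SignalTrack, path: str | Path, sig_digits: int = 5) -> None:
    """Write a track as bedGraph, merging adjacent equal-valued runs."""
    with open(path, "w") as fh:
        for chrom in track.layout.chrom_names:
            cs = track.chroms[chrom]
            prev_val = None
            run_start = 0.0
            for i, v in enumerate(cs.values):
                vfmt = float(f"%.{sig_digits}g" % v)
                if prev_val is None:
                    prev_val, run_start = vfmt, cs.bounds[i]
                elif vfmt != prev_val:
                    fh.write(f"{chrom}\t{int(run_start)}\t{int(cs.bounds[i])}\t{prev_val:g}\n")
                    prev_val, run_start = vfmt, cs.bounds[i]
            if prev_val is not None:
                fh.write(f"{chrom}\t{int(run_start)}\t{int(cs.bounds[-1])}\t{prev_val:g}\n")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def normalize_global_mean(track: SignalTrack) -> SignalTrack:
    """Rescale so the genome-wide length-weighted mean is exactly 1."""
    gm = track.genome_mean
    if gm <= 0:
        raise ValueError("cannot normalize a track with non-positive genome mean")
    return track.scaled(1.0 / gm)


def region_mean(track: SignalTrack, region: Region) -> float:
    """Length-weighted mean of the signal over one region."""
    length = track.layout.length_of(region.chrom)
    if not 0 <= region.start < region.end <= length:
        raise ValueError(f"region [{region.start}, {region.end}) invalid on {region.chrom}")
    return float(track.mean_over(region.chrom, region.start, region.end))


def bin_track(track: SignalTrack, bin_width: int) -> SignalTrack:
    """Average the signal into fixed-width bins (last bin per chromosome may
    be short).  Conserves the genome-wide integral exactly."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    segments = {}
    for chrom, length in zip(track.layout.chrom_names, track.layout.chrom_lengths):
        edges = np.arange(0, length, bin_width, dtype=np.float64)
        edges = np.append(edges, float(length))
        means = track.chroms[chrom].integral(edges[:-1], edges[1:]) / np.diff(edges)
        segments[chrom] = (edges, means)
    return SignalTrack.from_arrays(track.layout, segments)


def distance_profile(track: SignalTrack, regions: RegionSet, anchor: str,
                     bin_width: int, per_domain: bool = False) -> ProfileCurve:
    """Mean signal as a function of distance from telomeres or centromeres.

    For ``anchor="telomere"`` each region is interpreted as one chromosome-arm
    domain: on a left arm the distance of position ``p`` from the telomere is
    ``p`` itself; on a right arm it is ``L - p - 1``, so a distance bin
    ``[d0, d1)`` maps back to genome interval ``[L - d1, L - d0)``.  Arm
    assignment uses the region midpoint relative to the chromosome midpoint.

    For ``anchor="centromere"`` distances are ``|p - centromere_mid|``
    (symmetric pooling of the two sides).

    By default the curve pools base pairs across all contributing regions
    (length-weighted); ``per_domain=True`` instead averages the per-domain
    curves with equal weight per domain.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    if anchor not in ("telomere", "centromere"):
        raise ValueError(f"unknown anchor {anchor!r}")

    # per-domain spans: (chrom, distance_start, distance_end, side)
    spans: list[tuple[str, float, float, str]] = []
    for r in regions:
        length = track.layout.length_of(r.chrom)
        if anchor == "telomere":
            mid = 0.5 * (r.start + r.end)
            if mid <= length / 2:  # left arm: d = p
                spans.append((r.chrom, r.start, r.end, "left"))
            else:  # right arm: d = L - p - 1 -> [d0, d1) <- [L-d1, L-d0)
                spans.append((r.chrom, length - r.end, length - r.start, "right"))
        else:
            cen = track.layout.centromere_of(r.chrom)
            # split into left/right of the centromere, both mapped to |d|
            if r.start < cen:
                s, e = r.start, min(r.end, cen)
                spans.append((r.chrom, cen - e, cen - s, "cen-left"))
            if r.end > cen:
                s, e = max(r.start, cen), r.end
                spans.append((r.chrom, s - cen, e - cen, "cen-right"))

    d_min = min(s[1] for s in spans)
    d_max = max(s[2] for s in spans)
    edges = np.arange(d_min, d_max, bin_width, dtype=float)
    edges = np.append(edges, float(d_max))

    def _domain_curve(span):
        chrom, ds, de, side = span
        lo = np.clip(edges[:-1], ds, de)
        hi = np.clip(edges[1:], ds, de)
        nbp = hi - lo
        # map distance interval [lo, hi) back to genome coordinates
        if side == "left":
            a, b = lo, hi
        elif side == "right":
            length = track.layout.length_of(chrom)
            a, b = length - hi, length - lo
        elif side == "cen-left":
            cen = track.layout.centromere_of(chrom)
            a, b = cen - hi, cen - lo
        else:
            cen = track.layout.centromere_of(chrom)
            a, b = cen + lo, cen + hi
        integ = np.zeros_like(nbp)
        mask = nbp > 0
        if mask.any():
            integ[mask] = track.chroms[chrom].integral(a[mask], b[mask])
        return integ, nbp

    if per_domain:
        curves = []
        nbp_tot = np.zeros(len(edges) - 1)
        for span in spans:
            integ, nbp = _domain_curve(span)
            with np.errstate(invalid="ignore"):
                curves.append(np.where(nbp > 0, integ / np.maximum(nbp, 1e-300), np.nan))
            nbp_tot += nbp
        arr = np.vstack(curves)
        mean = np.nanmean(arr, axis=0)
    else:
        integ_tot = np.zeros(len(edges) - 1)
        nbp_tot = np.zeros(len(edges) - 1)
        for span in spans:
            integ, nbp = _domain_curve(span)
            integ_tot += integ
            nbp_tot += nbp
        with np.errstate(invalid="ignore"):
            mean = np.where(nbp_tot > 0, integ_tot / np.maximum(nbp_tot, 1e-300), np.nan)

    bins = pd.DataFrame({
        "distance_start": edges[:-1].astype(np.int64),
        "distance_end": edges[1:].astype(np.int64),
        "mean": mean,
        "n_bp": nbp_tot.astype(np.int64),
    })
    return ProfileCurve(anchor=anchor, bin_width=bin_width, bins=bins)
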