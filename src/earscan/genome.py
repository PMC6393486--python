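"""Genome coordinate frame and region constructors.

The analyses in this package are all defined relative to a small set of
chromosomal landmark regions on the 16 nuclear chromosomes of budding yeast:

* **EARs** (end-adjacent regions): the ~90-kb domains 20--110 kb from each
  chromosome end that retain axis proteins and DSB activity in late meiotic
  prophase.  One per chromosome arm, 32 per genome.
* **Interstitial regions**: everything further than 110 kb from either end;
  one per chromosome.
* **Centromere windows**: fixed-width windows centered on the centromere
  midpoint (2 kb up to 50 kb depending on the analysis).
* **rDNA flanks**: 100-kb domains on either side of the ribosomal DNA array
  on chromosome XII.

All coordinates are 0-based, half-open (bedGraph/BED native).  A quoted span
such as "20--110 kb from the telomere" maps to ``[20000, 110000)`` measured
from the assembly end of the chromosome.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "Region",
    "RegionSet",
    "LayoutError",
    "load_layout",
    "define_ears",
    "define_interstitial",
    "define_centromere_windows",
    "define_rdna_flanks",
    "eligible_territory",
]


class LayoutError(ValueError):
    """Raised for malformed or internally inconsistent genome layouts."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names, lengths, centromere midpoints and the rDNA interval.

    Parameters
    ----------
    chrom_names
        Ordered, unique chromosome identifiers.
    chrom_lengths
        Length in bp of each chromosome (parallel to ``chrom_names``).
    centromere_mid
        Centromere midpoint coordinate per chromosome.
    rdna_interval
        ``(chrom, start, end)`` of the ribosomal DNA array, or ``None`` for
        layouts without one.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    centromere_mid: tuple[int, ...]
    rdna_interval: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise LayoutError("duplicate chromosome names in layout")
        if not (len(self.chrom_names) == len(self.chrom_lengths) == len(self.centromere_mid)):
            raise LayoutError("layout fields have mismatched lengths")
        for name, length, cen in zip(self.chrom_names, self.chrom_lengths, self.centromere_mid):
            if length <= 0:
                raise LayoutError(f"chromosome {name} has non-positive length {length}")
            if not 0 <= cen < length:
                raise LayoutError(
                    f"centromere midpoint {cen} outside chromosome {name} (length {length})"
                )
        if self.rdna_interval is not None:
            chrom, start, end = self.rdna_interval
            if chrom not in self.chrom_names:
                raise LayoutError(f"rDNA chromosome {chrom!r} not in layout")
            if not 0 <= start < end <= self.length_of(chrom):
                raise LayoutError(f"rDNA interval [{start}, {end}) outside chromosome {chrom}")

    # -- lookups ---------------------------------------------------------

    def length_of(self, chrom: str) -> int:
        return self.chrom_lengths[self.chrom_names.index(chrom)]

    def centromere_of(self, chrom: str) -> int:
        return self.centromere_mid[self.chrom_names.index(chrom)]

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_names)

    @property
    def genome_size(self) -> int:
        return int(sum(self.chrom_lengths))

    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def scaled(self, factor: float) -> "GenomeLayout":
        """Return a layout with all coordinates multiplied by ``factor``.

        Used for scaled-down simulation studies; window-to-chromosome length
        ratios (which govern bootstrap behavior) are invariant under scaling.
        """
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        rdna = self.rdna_interval
        if rdna is not None:
            rdna = (rdna[0], int(round(rdna[1] * factor)), int(round(rdna[2] * factor)))
        return GenomeLayout(
            chrom_names=self.chrom_names,
            chrom_lengths=tuple(max(1, int(round(l * factor))) for l in self.chrom_lengths),
            centromere_mid=tuple(int(c * factor) for c in self.centromere_mid),
            rdna_interval=rdna,
        )


@dataclass(frozen=True)
class Region:
    """A labeled half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid region [{self.start}, {self.end}) on {self.chrom}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """An ordered collection of :class:`Region` with provenance metadata."""

    regions: list[Region]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    @property
    def total_width(self) -> int:
        return sum(r.width for r in self.regions)

    def on_chrom(self, chrom: str) -> list[Region]:
        return [r for r in self.regions if r.chrom == chrom]

    def chroms(self) -> list[str]:
        seen: list[str] = []
        for r in self.regions:
            if r.chrom not in seen:
                seen.append(r.chrom)
        return seen

    # -- BED round trip --------------------------------------------------

    def to_bed(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(r.chrom, r.start, r.end, r.label or ".") for r in self.regions],
            columns=["chrom", "start", "end", "name"],
        )
        df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path, layout: GenomeLayout | None = None) -> "RegionSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
        )
        regions = []
        for row in df.itertuples(index=False):
            if layout is not None:
                if row.chrom not in layout.chrom_names:
                    raise LayoutError(f"BED chromosome {row.chrom!r} not in layout")
                if row.end > layout.length_of(row.chrom):
                    raise LayoutError(
                        f"BED interval [{row.start}, {row.end}) exceeds {row.chrom} length"
                    )
            label = "" if str(row.name) == "." else str(row.name)
            regions.append(Region(row.chrom, int(row.start), int(row.end), label))
        return cls(regions, provenance={"constructor": "from_bed", "path": str(path)})


# ---------------------------------------------------------------------------
# layout loading
# ---------------------------------------------------------------------------

_BUNDLED = {"yeast": "yeast_layout.tsv", "saccer": "yeast_layout.tsv"}


def load_layout(source: str | Path) -> GenomeLayout:
    """Load a :class:`GenomeLayout` from a TSV file or a bundled name.

    The bundled ``"yeast"`` layout carries the standard 16 *S. cerevisiae*
    chromosomes with the rDNA array at chrXII:451,000--471,000.

    The file format is tab-delimited with ``#`` comments and columns
    ``chrom  length  centromere_mid  [rdna_start  rdna_end]``; at most one
    row may carry the optional rDNA columns.
    """
    key = str(source).lower()
    if key in _BUNDLED:
        ref = importlib.resources.files("earscan.data") / _BUNDLED[key]
        with importlib.resources.as_file(ref) as p:
            return _parse_layout_file(p)
    path = Path(source)
    if not path.exists():
        raise LayoutError(f"layout source {source!r} is neither a file nor a bundled name")
    return _parse_layout_file(path)


def _parse_layout_file(path: Path) -> GenomeLayout:
    names: list[str] = []
    lengths: list[int] = []
    cens: list[int] = []
    rdna: tuple[str, int, int] | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) not in (3, 5):
            raise LayoutError(f"{path}:{lineno}: expected 3 or 5 columns, got {len(parts)}")
        try:
            chrom, length, cen = parts[0], int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise LayoutError(f"{path}:{lineno}: non-integer coordinate ({exc})") from None
        names.append(chrom)
        lengths.append(length)
        cens.append(cen)
        if len(parts) == 5:
            if rdna is not None:
                raise LayoutError(f"{path}:{lineno}: multiple rDNA intervals")
            rdna = (chrom, int(parts[3]), int(parts[4]))
    if not names:
        raise LayoutError(f"{path}: no chromosomes found")
    return GenomeLayout(tuple(names), tuple(lengths), tuple(cens), rdna)


# ---------------------------------------------------------------------------
# region constructors
# ---------------------------------------------------------------------------

def _clip(start: int, end: int, length: int) -> tuple[int, int]:
    return max(0, start), min(length, end)


def define_ears(layout: GenomeLayout, proximal: int = 20000, distal: int = 110000) -> RegionSet:
    """End-adjacent regions: ``[proximal, distal)`` from each chromosome end.

    With the defaults, each chromosome contributes a left-arm region
    ``[20000, 110000)`` and a right-arm region ``[L-110000, L-20000)``:
    32 domains on the 16-chromosome yeast layout.

    If ``distal`` reaches past the chromosome midpoint the two arm regions
    overlap; they are kept as two regions and flagged in provenance, never
    merged.
    """
    if not 0 <= proximal < distal:
        raise ValueError("require 0 <= proximal < distal")
    regions: list[Region] = []
    overlapping: list[str] = []
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
        ls, le = _clip(proximal, distal, length)
        rs, re = _clip(length - distal, length - proximal, length)
        if ls < le:
            regions.append(Region(chrom, ls, le, "EAR-left"))
        if rs < re:
            regions.append(Region(chrom, rs, re, "EAR-right"))
        if ls < le and rs < re and le > rs:
            overlapping.append(chrom)
    return RegionSet(
        regions,
        provenance={
            "constructor": "define_ears",
            "proximal": proximal,
            "distal": distal,
            "overlapping_arms": overlapping,
        },
    )


def define_interstitial(layout: GenomeLayout, margin: int = 110000) -> RegionSet:
    """Interstitial territory: ``[margin, L - margin)`` per chromosome.

    Chromosomes with ``L <= 2 * margin`` contribute no region; they are
    recorded under ``provenance["dropped"]``.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    regions: list[Region] = []
    dropped: list[str] = []
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
        if length > 2 * margin:
            regions.append(Region(chrom, margin, length - margin, "interstitial"))
        else:
            dropped.append(chrom)
    return RegionSet(
        regions,
        provenance={"constructor": "define_interstitial", "margin": margin, "dropped": dropped},
    )


def define_centromere_windows(layout: GenomeLayout, width: int) -> RegionSet:
    """Windows of ``width`` bp centered on each centromere midpoint.

    Supports the 2-kb, 6-kb, 40-kb and 50-kb pericentromeric analyses;
    windows are clipped to chromosome bounds.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    half = width // 2
    regions = []
    for chrom, length, cen in zip(layout.chrom_names, layout.chrom_lengths, layout.centromere_mid):
        s, e = _clip(cen - half, cen - half + width, length)
        regions.append(Region(chrom, s, e, f"cen{width}"))
    return RegionSet(
        regions, provenance={"constructor": "define_centromere_windows", "width": width}
    )


def define_rdna_flanks(layout: GenomeLayout, width: int = 100000) -> RegionSet:
    """The two ``width``-bp domains immediately flanking the rDNA array."""
    if width <= 0:
        raise ValueError("width must be positive")
    if layout.rdna_interval is None:
        raise LayoutError("layout has no rDNA interval; cannot build rDNA flanks")
    chrom, rstart, rend = layout.rdna_interval
    length = layout.length_of(chrom)
    ls, le = _clip(rstart - width, rstart, length)
    rs, re = _clip(rend, rend + width, length)
    regions = []
    if ls < le:
        regions.append(Region(chrom, ls, le, "rdna-flank-left"))
    if rs < re:
        regions.append(Region(chrom, rs, re, "rdna-flank-right"))
    return RegionSet(regions, provenance={"constructor": "define_rdna_flanks", "width": width})


# ---------------------------------------------------------------------------
# interval set arithmetic
# ---------------------------------------------------------------------------

def merged_intervals(regions: Iterable[Region]) -> dict[str, np.ndarray]:
    """Union of regions per chromosome as an ``(n, 2)`` array of merged runs."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    out: dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged, dtype=np.int64)
    return out


def eligible_territory(layout: GenomeLayout, exclusions: RegionSet) -> RegionSet:
    """Per-chromosome complement of the exclusion union.

    Total eligible width always equals genome size minus the width of the
    merged exclusion union (checked by the test suite as a property).
    """
    merged = merged_intervals(exclusions)
    regions: list[Region] = []
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
        cursor = 0
        for s, e in merged.get(chrom, np.empty((0, 2), dtype=np.int64)):
            s, e = _clip(int(s), int(e), length)
            if cursor < s:
                regions.append(Region(chrom, cursor, s, "eligible"))
            cursor = max(cursor, e)
        if cursor < length:
            regions.append(Region(chrom, cursor, length, "eligible"))
    return RegionSet(
        regions,
        provenance={"constructor": "eligible_territory", "n_exclusions": len(exclusions)},
    )
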