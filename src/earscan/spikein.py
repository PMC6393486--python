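"""Spike-in (SNP-ChIP style) normalization of total ChIP levels.

When a fixed proportion (10--20%) of crosslinked cells from a polymorphic
spike-in strain is added to each sample before immunoprecipitation, reads
mapping uniquely to the spike-in genome provide an internal yardstick: the
ratio of experimental-genome to spike-in-genome reads in the ChIP library,
corrected by the same ratio in the input library (which measures the actual
mixing proportion), is proportional to the total amount of target protein
bound in the experimental genome.  Dividing a sample's factor by a reference
sample's factor puts both on a common absolute scale, turning mean-1
normalized regional enrichments into comparable absolute levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpikeInCounts", "SpikeInComparison", "norm_factor", "relative_level",
           "scale_regional_means", "read_counts_table", "average_replicate_factors"]


@dataclass(frozen=True)
class SpikeInCounts:
    """Unique-mapping read counts of one sample's ChIP and input libraries."""

    sample: str
    chip_target_reads: int
    chip_spike_reads: int
    input_target_reads: int
    input_spike_reads: int

    def __post_init__(self) -> None:
        for f in ("chip_target_reads", "chip_spike_reads",
                  "input_target_reads", "input_spike_reads"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")

    @property
    def chip_spike_fraction(self) -> float:
        return self.chip_spike_reads / (self.chip_spike_reads + self.chip_target_reads)


@dataclass(frozen=True)
class SpikeInComparison:
    """A sample's spike-in level relative to a reference sample."""

    sample: str
    reference: str
    factor: float
    reference_factor: float

    @property
    def relative_level(self) -> float:
        return self.factor / self.reference_factor

    @property
    def percent_change(self) -> float:
        """100 x (relative_level - 1); -32 reads as a 32% reduction."""
        return 100.0 * (self.relative_level - 1.0)


def norm_factor(counts: SpikeInCounts, input_corrected: bool = True) -> float:
    """Spike-in normalization factor of one sample.

    ``(chip_target / chip_spike) / (input_target / input_spike)``: the ChIP
    target-to-spike read ratio corrected by the actual mixing ratio measured
    in the input library.  ``input_corrected=False`` returns the uncorrected
    ChIP-only ratio (sensitivity-check variant).
    """
    if counts.chip_spike_reads == 0 or (input_corrected and counts.input_spike_reads == 0):
        raise ValueError(f"sample {counts.sample!r}: zero spike-in reads (spike-in failed)")
    if counts.chip_target_reads == 0 or (input_corrected and counts.input_target_reads == 0):
        raise ValueError(f"sample {counts.sample!r}: zero target reads")
    chip_ratio = counts.chip_target_reads / counts.chip_spike_reads
    if not input_corrected:
        return chip_ratio
    input_ratio = counts.input_target_reads / counts.input_spike_reads
    return chip_ratio / input_ratio


def relative_level(sample_factor: float, reference_factor: float,
                   sample: str = "sample", reference: str = "reference") -> SpikeInComparison:
    """Sample level relative to reference (relative_level 0.68 = 32% reduction)."""
    if sample_factor <= 0 or reference_factor <= 0:
        raise ValueError("factors must be positive")
    return SpikeInComparison(sample=sample, reference=reference,
                             factor=sample_factor, reference_factor=reference_factor)


def average_replicate_factors(replicates: list[SpikeInCounts],
                              input_corrected: bool = True) -> float:
    """Mean of per-replicate normalization factors."""
    if not replicates:
        raise ValueError("no replicates")
    return float(np.mean([norm_factor(c, input_corrected) for c in replicates]))


def scale_regional_means(means: pd.Series | pd.DataFrame,
                         comparison: SpikeInComparison) -> pd.Series | pd.DataFrame:
    """Put mean-1-normalized regional means on the reference's absolute scale.

    Every value is multiplied by the sample's relative level; ratios between
    region classes within the sample are preserved.
    """
    return means * comparison.relative_level


def read_counts_table(path: str | Path) -> dict[str, SpikeInCounts]:
    """Read a tab-delimited table ``sample chip_target chip_spike input_target
    input_spike`` into :class:`SpikeInCounts` keyed by sample id."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["sample", "chip_target", "chip_spike", "input_target", "input_spike"]
    if list(df.columns[:5]) != required:
        raise ValueError(f"counts table must have columns {required}")
    return {row.sample: SpikeInCounts(str(row.sample), int(row.chip_target),
                                      int(row.chip_spike), int(row.input_target),
                                      int(row.input_spike))
            for row in df.itertuples(index=False)}
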