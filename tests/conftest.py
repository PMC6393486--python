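import numpy as np
import pytest

from earscan import GenomeLayout, RegionSet, SignalTrack, load_layout


@pytest.fixture(scope="session")
def yeast_layout():
    return load_layout("yeast")


@pytest.fixture
def toy_layout():
    """Single 300-kb chromosome with a mid-chromosome centromere."""
    return GenomeLayout(("toy",), (300000,), (150000,))


@pytest.fixture
def three_chrom_layout():
    """Three chromosomes of distinct lengths; rDNA on the middle one."""
    return GenomeLayout(
        ("chrA", "chrB", "chrC"),
        (300000, 500000, 400000),
        (150000, 200000, 120000),
        rdna_interval=("chrB", 300000, 320000),
    )


@pytest.fixture
def step_track(toy_layout):
    """2.0 on the first 100 kb, 1.0 on the rest of the toy chromosome."""
    return SignalTrack.from_arrays(
        toy_layout,
        {"toy": (np.array([0.0, 100000.0, 300000.0]), np.array([2.0, 1.0]))},
    )


def brute_force_region_mean(track: SignalTrack, chrom: str, start: int, end: int) -> float:
    """Per-base-pair averaging oracle (exact for piecewise-constant tracks)."""
    cs = track.chroms[chrom]
    positions = np.arange(start, end)
    idx = np.searchsorted(cs.bounds, positions, side="right") - 1
    return float(cs.values[idx].mean())
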