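"""Shared fixtures: a small genome, toy tracks and a planted survival cohort."""

import numpy as np
import pytest

from svhot.core import Genome, IntervalTrack
from svhot.simulate import SimulationConfig, simulate_index_cohort


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    """Two chromosomes, 1 Mb each."""
    return Genome.from_sizes({"chr1": 1_000_000, "chr2": 1_000_000})


@pytest.fixture(scope="session")
def hundred_mb_genome() -> Genome:
    """Single 100-Mb chromosome used by the calibration simulations."""
    return Genome.from_sizes({"chr1": 100_000_000})


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_element_track(
    element_class: str = "E",
    n_elements: int = 500,
    width: int = 10_000,
    spacing: int = 200_000,
    chrom: str = "chr1",
) -> IntervalTrack:
    """Evenly spaced fixed-width elements (5 Mb total at the defaults)."""
    starts = np.arange(n_elements, dtype=np.int64) * spacing + spacing // 2
    return IntervalTrack(
        element_class, [chrom] * n_elements, starts, starts + width, merged=True
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """200 patients, index values uniform on (0, 3), true thresholds
    (1.0, 2.0), Medium-group hazard 10x Low/High, 20% censoring."""
    cfg = SimulationConfig(seed=7, n_samples=200)
    values, records = simulate_index_cohort(cfg)
    return cfg, values, records
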