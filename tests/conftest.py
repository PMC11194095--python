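import numpy as np
import pytest

from zgakit.simulate import SimulationConfig


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast, small-genome configuration for IO/CLI/determinism tests."""
    base = dict(
        seed=seed,
        chrom_sizes={"chr1": 6_000_000, "chr2": 5_000_000},
        n_genes=120,
        n_repeats=80,
        fragments_per_sample=2_000,
        deposition_fragments=5_000,
        total_contacts=200_000,
        tads_per_chrom=2,
        tad_length_bins=(4, 6),
        frap_curves_per_sample=5,
        replicates=2,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def config_small() -> SimulationConfig:
    return small_config()
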