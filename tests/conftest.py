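import numpy as np
import pytest

from phenogan import benchmark
from phenogan.chipio import ChipDataset, ImageChip
from phenogan.synthchips import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A fast 32-pixel generator configuration for unit tests."""
    return SynthConfig(chip_size=32, n_chips=40, positive_fraction=0.5,
                       canopy_radius_range=(8.0, 12.0),
                       panicle_size_range=(1.5, 3.0), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> ChipDataset:
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def benchmark_runs():
    """Three seeds of the scaled-down label-efficiency experiment.

    Session-scoped because each seed trains the semi-supervised GAN plus two
    CNN fits; the result is shared by the label-efficiency and activation-map
    analyses.
    """
    return [benchmark.run_label_efficiency(seed) for seed in (1, 2, 3)]


def make_plain_dataset(n: int, side: int = 8, positive_fraction: float = 0.5,
                       seed: int = 0) -> ChipDataset:
    """Cheap all-grey dataset for split/budget arithmetic tests."""
    rng = np.random.default_rng(seed)
    n_pos = int(round(positive_fraction * n))
    labels = np.zeros(n, dtype=np.int64)
    labels[:n_pos] = 1
    labels = labels[rng.permutation(n)]
    px = np.full((side, side, 3), 0.5, dtype=np.float32)
    chips = [ImageChip(px.copy()) for _ in range(n)]
    return ChipDataset(chips=chips, labels=labels,
                       ids=[f"c{i:05d}" for i in range(n)])
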