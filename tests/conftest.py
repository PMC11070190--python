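import pytest

from symbiotrace.segmentation import SegmentationParams, segment_cell, segment_compartments
from symbiotrace.synthetic_data import SimConfig, simulate_population


@pytest.fixture(scope="session")
def config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def seg_params():
    return SegmentationParams()


@pytest.fixture(scope="session")
def small_population(config):
    """Ten simulated labeled cells shared across read-only tests."""
    return simulate_population(config, 10)


@pytest.fixture(scope="session")
def segmented_cell(small_population, seg_params):
    """(image, truth, mask) for the first simulated cell."""
    image, truth = small_population[0]
    cell = segment_cell(image, seg_params)
    mask = segment_compartments(image, cell, seg_params)
    return image, truth, mask
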