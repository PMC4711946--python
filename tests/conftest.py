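import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from vesselquant import VesselSpec, generate_vessel_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_vessel():
    """A defect-free synthetic vessel image with ground truth."""
    spec = VesselSpec(smf_fraction=0.3, n_folds=0, n_blood=0, n_dust=0, seed=11)
    rgb, truth = generate_vessel_image(spec)
    return spec, rgb, truth


@pytest.fixture
def default_vessel():
    """A synthetic vessel with the default folds/blood/dust defects."""
    spec = VesselSpec(smf_fraction=0.4, seed=5)
    rgb, truth = generate_vessel_image(spec)
    return spec, rgb, truth
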