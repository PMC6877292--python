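import numpy as np
import pytest

import bbbflux as bf
from bbbflux.synthetic import NoiseParams, small_tree_config


@pytest.fixture(scope="session")
def small_tree():
    """Compact deterministic vessel tree shared across tests."""
    return bf.generate_vessel_tree(small_tree_config(), seed=11)


@pytest.fixture(scope="session")
def default_tree():
    return bf.generate_vessel_tree(bf.TreeConfig(), seed=1)


@pytest.fixture(scope="session")
def noiseless_wt_session(small_tree):
    """Three-tracer WT session without noise (float32 stack)."""
    truth = bf.default_ground_truth("WT", noise=NoiseParams.none())
    return bf.simulate_tracer_session(
        small_tree, bf.default_tracer_schedule(), truth
    )
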