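import numpy as np
import pytest

import squigmeth as sq
from squigmeth.features import FeatureConfig, extract_examples


@pytest.fixture(scope="session")
def sim_setup():
    """Small shared simulation: reference with islands, truth, separable pore."""
    config = sq.SimConfig(reference_length=6000, n_islands=2, island_length=400, seed=7)
    reference, truth = sq.simulate_reference(config)
    pore = sq.build_pore_model(k=1, mod_shift=1.0, seed=3, levels="spaced")
    return config, reference, truth, pore


@pytest.fixture(scope="session")
def clean_config():
    """Error-free basecalling variant of the shared simulation config."""
    return sq.SimConfig(
        reference_length=6000,
        n_islands=2,
        island_length=400,
        p_substitution=0.0,
        p_insertion=0.0,
        p_deletion=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def feature_config():
    return FeatureConfig(window=15, mode="reference")


def make_examples(reference, truth, pore, config, feature_config, n, seed0=0, length=800):
    """Simulate reads until at least n site examples are extracted."""
    examples = []
    seed = seed0
    while len(examples) < n:
        bundle = sq.simulate_read(
            reference, truth, pore, config, seed=seed, length=length, read_id=f"r{seed}"
        )
        examples.extend(extract_examples(bundle, reference, feature_config))
        seed += 1
    return examples


@pytest.fixture(scope="session")
def example_factory():
    return make_examples


@pytest.fixture(scope="session")
def small_examples(sim_setup, feature_config):
    config, reference, truth, pore = sim_setup
    return make_examples(reference, truth, pore, config, feature_config, 300)
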