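import dataclasses

import numpy as np
import pytest

from fnirspect import (
    SyntheticConfig,
    clean_config,
    default_channel_map,
    default_oscillators,
    generate_recording,
)


@pytest.fixture(scope="session")
def channel_map():
    return default_channel_map()


@pytest.fixture(scope="session")
def clean_cognitive_stationary():
    """Clean cognitive recording with stationary (non-wandering)
    oscillators: the fixture for end-to-end identity checks."""
    osc = [dataclasses.replace(o, wander=False) for o in default_oscillators()]
    cfg = clean_config(
        SyntheticConfig(protocol="cognitive", n_subjects=1, oscillators=osc, seed=5)
    )
    rec, truth = generate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def clean_hyper():
    """One clean (noise-, drift-, artifact-free) hypercapnic recording."""
    cfg = clean_config(SyntheticConfig(protocol="hypercapnic", n_subjects=1, seed=5))
    rec, truth = generate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def noisy_hyper():
    """One hypercapnic recording under the default study conditions."""
    cfg = SyntheticConfig(protocol="hypercapnic", n_subjects=1, seed=6)
    rec, truth = generate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
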