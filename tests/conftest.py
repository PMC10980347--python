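import dataclasses

import numpy as np
import pandas as pd
import pytest

import saltgrn as sg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_matrix():
    """4 genes x 6 samples, two groups of 3."""
    data = np.array(
        [
            [1.0, 2.0, 3.0, 2.0, 3.0, 4.0],
            [5.0, 5.5, 4.5, 5.0, 5.5, 4.5],
            [2.0, 2.1, 1.9, 8.0, 8.1, 7.9],
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        ]
    )
    return pd.DataFrame(
        data,
        index=["gA", "gB", "gC", "gD"],
        columns=["a1", "a2", "a3", "b1", "b2", "b3"],
    )


@pytest.fixture
def single_regulator_spec():
    """Noiseless experiment with one stress-specific regulator of effect 2."""
    return sg.GrnSpec(
        true_regulators={"TF005": sg.RegulatorEffect(beta=2.0, condition="stress", activation_time=3.0)},
        n_genes=12,
        noise_sd=0.0,
        seed=3,
    )


@pytest.fixture
def small_signal_experiment():
    """Small panel with a strong stress regulator and mild noise."""
    spec = sg.GrnSpec(
        true_regulators={"TF005": sg.RegulatorEffect(beta=2.0, condition="stress", activation_time=3.0)},
        n_genes=15,
        noise_sd=0.3,
        seed=11,
    )
    em, truth = sg.simulate_expression(spec)
    return spec, em, truth


@pytest.fixture
def fast_params():
    """Engine parameters scaled for unit-test speed."""
    return sg.InferenceParams(max_stages=300, seed=0)
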