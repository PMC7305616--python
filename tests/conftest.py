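"""Shared fixtures: small trained reference models on synthetic data."""

from __future__ import annotations

import numpy as np
import pytest

import gradpath as gp


@pytest.fixture(scope="session")
def tabular():
    """Two-class tabular data with 4 planted features among 30."""
    return gp.synth_tabular(n=200, p=30, n_informative=4, effect_size=5.0,
                            block_size=3, block_r=0.9, seed=1)


@pytest.fixture(scope="session")
def trained(tabular):
    """Reference codec + predictor trained on the tabular fixture."""
    codec, predictor = gp.train_reference_models(
        tabular.features.to_numpy(), tabular.labels,
        gp.ModelConfig(q=5, ae_hidden=(32,), head_hidden=(8,),
                       ae_epochs=250, head_epochs=250),
        seed=2,
    )
    return codec, predictor


@pytest.fixture(scope="session")
def linear_model():
    """Exactly linear prediction function with known coefficients."""
    w = np.array([3.0, -1.5, 0.5, 2.0])
    return w, gp.FunctionModel(lambda x: float(w @ x), p=4, grad=lambda x: w)
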