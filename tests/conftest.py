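"""Shared fixtures: generated datasets and (expensive) trained forecasters.

The trained-model fixtures are session-scoped so that the forecasting,
control and acceptance tests share one training run each.  Training sizes
are desk-scale: training samples are capped and epochs limited, while
architecture, optimizer, batch size and loss follow the deployed
configuration.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from vibrofeed import forecasting as fc
from vibrofeed import synthetic as syn


@pytest.fixture(scope="session")
def full_dataset():
    """The default 408-trial factorial dataset (master seed 7)."""
    return syn.generate_dataset(master_seed=7)


@pytest.fixture(scope="session")
def scalar_lstm(full_dataset):
    """Scalar-mode LSTM trained on the 408-trial dataset (stride 10)."""
    data = fc.build_supervised(full_dataset.traces, stride=10, mode="scalar")
    tcfg = fc.TrainConfig(seed=0, max_epochs=10, max_train_samples=3000)
    model = fc.train_forecaster(data, fc.ModelConfig(arch="lstm"), tcfg)
    return model, data


@pytest.fixture(scope="session")
def noiseless_scalar_lstm():
    """Scalar-mode LSTM trained on fully deterministic (noiseless) trials."""
    ds = syn.generate_dataset(
        design=syn.default_design(replicates=1), master_seed=3, noiseless=True
    )
    data = fc.build_supervised(ds.traces, stride=5, mode="scalar")
    tcfg = fc.TrainConfig(seed=1, max_epochs=12, max_train_samples=2000)
    model = fc.train_forecaster(data, fc.ModelConfig(arch="lstm"), tcfg)
    return model, data


@pytest.fixture(scope="session")
def trajectory_lstm():
    """Trajectory-mode LSTM used by the closed-loop control tests."""
    ds = syn.generate_dataset(design=syn.default_design(replicates=2), master_seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = fc.build_supervised(ds.traces, stride=12, mode="trajectory")
    tcfg = fc.TrainConfig(seed=0, max_epochs=12, max_train_samples=2500)
    model = fc.train_forecaster(data, fc.ModelConfig(arch="lstm", output_dim=50), tcfg)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
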