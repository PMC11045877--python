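"""Shared fixtures: noiseless and noisy simulated cells with ground truth."""

from __future__ import annotations

import numpy as np
import pytest

import biadquant as bq
from biadquant.simulate import suggested_thresholds


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noiseless_config():
    """Top-hat, noise-free cell with per-spot ratio 0.5 (exact-recovery mode)."""
    return bq.SimulationConfig(
        noise=bq.NoiseConfig.off(),
        modification_fraction=1.0,
        biad_gain=0.5,
        seed=7,
    )


@pytest.fixture
def noiseless_cell(noiseless_config):
    return bq.simulate_cell(noiseless_config)


def quantify_sim(sim, config, options=None):
    """Quantify one simulated cell with its ground-truth-implied thresholds."""
    thr = bq.ThresholdPair(*suggested_thresholds(config))
    return bq.quantify_cell(sim.image, thr, condition="sim", options=options)


def snr10_config(**overrides):
    """Noisy configuration at per-pixel spot signal-to-noise ratio 10.

    Marker spot amplitude 200 photons over a 100-photon nuclear base with
    Poisson shot noise plus read sigma 10: noise sd at the spot is
    sqrt(300 + 100) = 20, so amplitude/sd = 10.
    """
    base = dict(
        marker_gain=1.25,
        copy_number=160,  # amplitude 200
        modification_fraction=1.0,
        biad_gain=0.5,  # true per-spot ratio 0.5
        noise=bq.NoiseConfig(poisson=True, read_sigma=10.0, offset=0.0),
    )
    base.update(overrides)
    return bq.SimulationConfig(**base)
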