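"""Shared fixtures: small synthetic cells and stimulus trains.

Everything is generated programmatically with fixed seeds; the medium-sized
recovery cell is session-scoped because several modules test against it.
"""

import numpy as np
import pytest

import erfield as ef


@pytest.fixture(scope="session")
def small_train():
    """6 electrodes, 10 Hz, 6k pulses: quick fixture for unit tests."""
    return ef.sample_white_noise_train(6000, 6, frequency_hz=10.0, seed=11)


@pytest.fixture(scope="session")
def small_design(small_train):
    return ef.build_design_matrix(small_train, window_ms=200.0)  # L=2, D=12


@pytest.fixture(scope="session")
def small_cell(small_design):
    gt = ef.make_ground_truth(1, 1, small_design.L,
                              small_design.n_electrodes, seed=21)
    resp = ef.simulate_responses(gt, small_design, seed=22)
    return gt, resp


@pytest.fixture(scope="session")
def medium_cell():
    """10 electrodes, 10 Hz, L=3, 1 exc + 1 sup, ~15k spikes."""
    train = ef.sample_white_noise_train(30000, 10, frequency_hz=10.0, seed=31)
    design = ef.build_design_matrix(train, window_ms=300.0)
    gt = ef.make_ground_truth(1, 1, design.L, 10, seed=32)
    resp = ef.simulate_responses(gt, design, seed=33)
    return design, gt, resp


@pytest.fixture(scope="session")
def medium_fit(medium_cell):
    design, gt, resp = medium_cell
    stc = ef.compute_stc(design, resp)
    model = ef.fit_gqm(design, resp, 1, 1, init=stc, seed=0)
    return design, gt, resp, stc, model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
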