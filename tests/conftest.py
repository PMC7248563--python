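"""Shared fixtures: phantoms and fitted maps reused across test modules.

Heavy objects (the standard 32x32x16 phantom and its noisy fits) are
session-scoped so the whole suite simulates and fits each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest

import relaxo as rx

STD_SEED = 1
PEAK_SNR = 50.0


@pytest.fixture(scope="session")
def std_spec() -> rx.PhantomSpec:
    return rx.PhantomSpec(grid_shape=(32, 32, 16), seed=STD_SEED)


@pytest.fixture(scope="session")
def std_labels(std_spec) -> rx.LabelVolume:
    return rx.make_label_phantom(std_spec)


@pytest.fixture(scope="session")
def std_truth(std_labels, std_spec):
    return rx.truth_maps(std_labels, std_spec)


@pytest.fixture(scope="session")
def noiseless_ir_series(std_truth):
    t1, _, pd_map = std_truth
    return rx.simulate_ir_series(
        t1, pd_map, rx.default_ir_protocol(), noise_sigma=0.0, seed=2
    )


@pytest.fixture(scope="session")
def noiseless_me_series(std_truth):
    _, t2, pd_map = std_truth
    return rx.simulate_multiecho_series(
        t2, pd_map, rx.default_multiecho_protocol(), noise_sigma=0.0, seed=3
    )


def _peak_sigma(t_map, pd_map, protocol, modality):
    """Noise scale for peak-SNR 50 relative to the series' own peak signal."""
    if modality == "ir":
        fg = pd_map > 0
        rec = np.abs(
            1.0 - 2.0 * np.exp(-protocol.times[None, :] / t_map[fg, None])
        )
        peak = float((pd_map[fg, None] * rec).max())
    else:
        peak = float(
            (pd_map[pd_map > 0, None]
             * np.exp(-protocol.times[None, :] / t_map[pd_map > 0, None])).max()
        )
    return peak / PEAK_SNR


@pytest.fixture(scope="session")
def noisy_ir_series(std_truth):
    t1, _, pd_map = std_truth
    prot = rx.default_ir_protocol()
    sigma = _peak_sigma(t1, pd_map, prot, "ir")
    return rx.simulate_ir_series(t1, pd_map, prot, noise_sigma=sigma, seed=4)


@pytest.fixture(scope="session")
def lm_t1_noisy_map(noisy_ir_series):
    return rx.fit_t1_map(noisy_ir_series, rx.FitOptions())


@pytest.fixture(scope="session")
def simplex_t1_noisy_map(noisy_ir_series):
    return rx.fit_t1_map(noisy_ir_series, rx.FitOptions(optimizer=rx.Optimizer.SIMPLEX))


@pytest.fixture(scope="session")
def tiny_spec() -> rx.PhantomSpec:
    return rx.PhantomSpec(grid_shape=(16, 16, 8), seed=5)


@pytest.fixture(scope="session")
def tiny_labels(tiny_spec) -> rx.LabelVolume:
    return rx.make_label_phantom(tiny_spec)
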