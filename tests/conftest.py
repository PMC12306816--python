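"""Shared fixtures: one default phantom acquisition and its reconstruction
products, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from snraware.gfactor import compute_gfactor_set
from snraware.phantom import PhantomConfig, simulate_acquisition
from snraware.recon import (apply_prewhitening, calibrate_grappa,
                            compute_prewhitener, estimate_coil_maps,
                            estimate_noise_covariance, kernel_to_unmixing,
                            reconstruct_snr_unit)


@pytest.fixture(scope="session")
def phantom_cfg() -> PhantomConfig:
    return PhantomConfig(seed=12345)


@pytest.fixture(scope="session")
def acquisition(phantom_cfg):
    """(noisy k-space, pre-scan, labels, true coil maps) at default settings."""
    return simulate_acquisition(phantom_cfg)


@pytest.fixture(scope="session")
def object_mask(acquisition):
    _, _, labels, _ = acquisition
    return (labels["body"][:, :, 0] | labels["blood"][:, :, 0]
            | labels["myocardium"][:, :, 0])


@pytest.fixture(scope="session")
def whitened(acquisition):
    ksp, prescan, _, _ = acquisition
    cov = estimate_noise_covariance(prescan)
    wt = compute_prewhitener(cov)
    return apply_prewhitening(ksp, wt), cov, wt


@pytest.fixture(scope="session")
def est_coil_maps(whitened, phantom_cfg):
    white, _, _ = whitened
    return estimate_coil_maps(white.acs, phantom_cfg.matrix_size)


@pytest.fixture(scope="session")
def unmix_r2(whitened, est_coil_maps, phantom_cfg):
    white, _, _ = whitened
    kern = calibrate_grappa(white.acs, accel=2)
    return kernel_to_unmixing(kern, est_coil_maps, phantom_cfg.matrix_size)


@pytest.fixture(scope="session")
def recon_r2(whitened, unmix_r2):
    white, _, _ = whitened
    return reconstruct_snr_unit(white, unmix_r2)


@pytest.fixture(scope="session")
def gset(whitened):
    white, _, _ = whitened
    return compute_gfactor_set(white, r_values=(2, 3, 4, 5, 6, 7, 8))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
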