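"""Shared fixtures: a 1D unit-interval setup mirroring the simulation preset."""

import numpy as np
import pytest

from diracfit import Domain, DiracMeasure, FidelitySpec, GaussianPSF, SamplingGrid, forward


@pytest.fixture
def domain1d():
    return Domain(np.array([0.0]), np.array([1.0]))


@pytest.fixture
def grid1d(domain1d):
    return SamplingGrid(domain1d, (64,))


@pytest.fixture
def psf1d():
    return GaussianPSF(np.array([0.07]))


@pytest.fixture
def single_spike():
    return DiracMeasure(np.array([[0.5]]), np.array([1.0]))


def make_noiseless_spec(m, psf, grid, kind="kl", b=0.01, alpha=1):
    """Fidelity spec whose acquisition is the exact forward image of ``m``."""
    y = forward(m, psf, grid) + b
    return FidelitySpec(kind, y, b, alpha=alpha)


@pytest.fixture
def noiseless_kl_spec(single_spike, psf1d, grid1d):
    return make_noiseless_spec(single_spike, psf1d, grid1d)
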