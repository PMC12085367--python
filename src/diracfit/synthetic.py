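"""Phantom and acquisition generators for the simulation studies.

The presets reproduce the standard benchmark conditions of gridless spike
deconvolution in fluorescence microscopy:

* ``sim1d`` — 6 spikes uniform on [0, 1], amplitudes uniform on [0.6, 1.4],
  Gaussian PSF sigma = 0.07, constant background 0.01, 64-sample grid.
* ``sim2d`` — 15 spikes on [0, 1]^2, amplitudes uniform on [0.5, 1.5],
  sigma = 0.07, background 0.05, 64 x 64 grid.
* ``sim3d`` — 7 spikes on [-1300, 1300]^2 x [-1000, 1000] nm, amplitudes
  uniform on [0.6, 1.4], anisotropic PSF (200, 200, 400) nm, background 0.5,
  40 x 40 x 8 voxels (65 nm lateral / 250 nm axial voxel size).

Acquisitions are pixelwise-independent Poisson draws with mean
``photon_scale * (Phi mu_gt + b)``, divided back by ``photon_scale`` so the
data stay in the model's intensity units (the expectation is exactly
``Phi mu_gt + b``).  ``photon_scale`` — the number of expected photon counts
per unit model intensity — is the knob that sets the noise level; the
default puts the peak pixel of a unit-amplitude spike at about 100 expected
counts.  A Gaussian-noise generator is included for the additive baseline
scenario, and ``background_mask`` builds the outer square-ring mask used by
the residual-target and background estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .forward import GaussianPSF, SamplingGrid, forward
from .measures import DiracMeasure, Domain

__all__ = [
    "ScenarioPreset",
    "preset",
    "default_photon_scale",
    "generate_ground_truth",
    "simulate_acquisition",
    "gaussian_noise_acquisition",
    "background_mask",
]


@dataclass(frozen=True)
class ScenarioPreset:
    """Everything needed to generate one phantom and its acquisition."""

    name: str
    domain: Domain
    shape: tuple
    n_spikes: int
    amplitude_range: tuple
    psf: GaussianPSF
    background: float
    photon_scale: float

    def __post_init__(self) -> None:
        lo, hi = self.amplitude_range
        if not 0 < lo <= hi:
            raise ValueError("amplitude range must be positive")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")

    @property
    def grid(self) -> SamplingGrid:
        return SamplingGrid(self.domain, self.shape)


def default_photon_scale(psf: GaussianPSF, peak_counts: float = 100.0) -> float:
    """Counts per unit intensity putting a unit spike's peak at ``peak_counts``."""
    return peak_counts / psf.peak


def preset(name: str, photon_scale: float | None = None) -> ScenarioPreset:
    """Build one of the named simulation presets (see module docstring)."""
    if name == "sim1d":
        psf = GaussianPSF(np.array([0.07]))
        return ScenarioPreset(
            name,
            Domain(np.array([0.0]), np.array([1.0])),
            (64,),
            6,
            (0.6, 1.4),
            psf,
            0.01,
            photon_scale if photon_scale is not None else default_photon_scale(psf),
        )
    if name == "sim2d":
        psf = GaussianPSF(np.array([0.07, 0.07]))
        return ScenarioPreset(
            name,
            Domain(np.zeros(2), np.ones(2)),
            (64, 64),
            15,
            (0.5, 1.5),
            psf,
            0.05,
            photon_scale if photon_scale is not None else default_photon_scale(psf),
        )
    if name == "sim3d":
        psf = GaussianPSF(np.array([200.0, 200.0, 400.0]))
        return ScenarioPreset(
            name,
            Domain(np.array([-1300.0, -1300.0, -1000.0]), np.array([1300.0, 1300.0, 1000.0])),
            (40, 40, 8),
            7,
            (0.6, 1.4),
            psf,
            0.5,
            photon_scale if photon_scale is not None else default_photon_scale(psf),
        )
    raise ValueError(f"unknown preset {name!r}")


def generate_ground_truth(
    scenario: ScenarioPreset, rng: np.random.Generator
) -> DiracMeasure:
    """Phantom with i.i.d. uniform positions on Omega and uniform amplitudes."""
    d = scenario.domain.dim
    pos = rng.uniform(
        scenario.domain.lower, scenario.domain.upper, size=(scenario.n_spikes, d)
    )
    lo, hi = scenario.amplitude_range
    amp = rng.uniform(lo, hi, size=scenario.n_spikes)
    return DiracMeasure(pos, amp)


def simulate_acquisition(
    m_gt: DiracMeasure, scenario: ScenarioPreset, rng: np.random.Generator
) -> np.ndarray:
    """Poisson acquisition in intensity units with expectation ``Phi mu_gt + b``."""
    mean = forward(m_gt, scenario.psf, scenario.grid) + scenario.background
    if np.any(mean < 0):
        raise ValueError("negative Poisson mean: check amplitudes and background")
    ps = scenario.photon_scale
    return rng.poisson(ps * mean).astype(float) / ps


def gaussian_noise_acquisition(
    m_gt: DiracMeasure,
    scenario: ScenarioPreset,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Additive-Gaussian acquisition ``Phi mu_gt + b + N(0, noise_sd^2)``."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    mean = forward(m_gt, scenario.psf, scenario.grid) + scenario.background
    if noise_sd == 0:
        return mean
    return mean + rng.normal(0.0, noise_sd, size=mean.shape)


def background_mask(grid: SamplingGrid, margin_fraction: float) -> np.ndarray:
    """Outer ring/shell indicator of fractional width ``margin_fraction``.

    A pixel belongs to the mask when its index lies within
    ``floor(margin_fraction * M_k)`` cells of either edge on any axis.
    """
    if not 0 < margin_fraction < 0.5:
        raise ValueError("margin_fraction must lie in (0, 0.5)")
    mask = np.zeros(grid.shape, dtype=bool)
    for k, M in enumerate(grid.shape):
        w = int(np.floor(margin_fraction * M))
        if w == 0:
            continue
        idx = np.arange(M)
        edge = (idx < w) | (idx >= M - w)
        shape = [1] * grid.dim
        shape[k] = M
        mask |= edge.reshape(shape)
    return mask
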