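"""Gaussian PSF measurement model on a regular sampling grid.

The forward operator maps a Dirac measure to the blurred intensity image

    (Phi mu)(s) = sum_i a_i * phi(s - x_i),

with ``phi`` a (possibly anisotropic, normalised) Gaussian point spread
function evaluated pointwise at the pixel centres of a regular grid.  The
adjoint field ``Phi* p`` is the continuous function

    (Phi* p)(x) = <p, phi(. - x)>_{L2(Omega)}

approximated by the midpoint quadrature carried by the grid.  All L2(Omega)
inner products in this package include the pixel measure, so fidelities,
certificates and regularisation paths are stable under grid refinement.

Positions are continuous physical coordinates throughout: spikes never snap
to pixel centres.  Because the number of spikes is small, Phi and Phi* are
evaluated directly from the kernel (no FFT), which is exact at arbitrary
off-grid positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .measures import DiracMeasure, Domain

__all__ = [
    "GaussianPSF",
    "SamplingGrid",
    "psf_eval",
    "forward",
    "adjoint_field",
    "adjoint_field_batch",
]


@dataclass(frozen=True)
class GaussianPSF:
    """Normalised Gaussian blur kernel with per-axis widths ``sigmas`` (> 0).

    ``phi(u) = prod_k (2 pi sigma_k^2)^{-1/2} exp(-u_k^2 / (2 sigma_k^2))``;
    the kernel integrates to one over R^d.
    """

    sigmas: np.ndarray

    def __post_init__(self) -> None:
        s = np.atleast_1d(np.asarray(self.sigmas, dtype=float))
        if np.any(s <= 0):
            raise ValueError("PSF widths must be strictly positive")
        object.__setattr__(self, "sigmas", s)

    @property
    def dim(self) -> int:
        return self.sigmas.size

    @property
    def peak(self) -> float:
        """Kernel value at its centre, ``prod_k (2 pi sigma_k^2)^{-1/2}``."""
        return float(np.prod(1.0 / (np.sqrt(2.0 * np.pi) * self.sigmas)))


@dataclass(frozen=True)
class SamplingGrid:
    """Regular cell-centred discretisation of the domain.

    Pixel centres follow the half-open convention
    ``centre_k(i) = lower_k + (i + 0.5) * (upper_k - lower_k) / M_k`` so the
    total quadrature weight ``pixel_measure * prod_k M_k`` equals the domain
    volume exactly.
    """

    domain: Domain
    shape: tuple

    def __post_init__(self) -> None:
        shp = tuple(int(s) for s in np.atleast_1d(self.shape))
        if len(shp) != self.domain.dim:
            raise ValueError("grid shape rank must match domain dimension")
        if any(s < 1 for s in shp):
            raise ValueError("each axis needs at least one sample")
        object.__setattr__(self, "shape", shp)

    @property
    def dim(self) -> int:
        return self.domain.dim

    @property
    def n_pixels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def pixel_measure(self) -> float:
        """Quadrature weight of one cell, ``prod_k (upper_k - lower_k) / M_k``."""
        ext = self.domain.upper - self.domain.lower
        return float(np.prod(ext / np.asarray(self.shape)))

    def axis_centres(self, k: int) -> np.ndarray:
        lo, hi = self.domain.lower[k], self.domain.upper[k]
        step = (hi - lo) / self.shape[k]
        return lo + (np.arange(self.shape[k]) + 0.5) * step

    @cached_property
    def points(self) -> np.ndarray:
        """All pixel centres as an (n_pixels, d) array, C-ordered."""
        axes = [self.axis_centres(k) for k in range(self.dim)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    def refined_points(self, factor: int) -> np.ndarray:
        """Centres of a ``factor``-times denser lattice (certificate search)."""
        fine = SamplingGrid(self.domain, tuple(s * factor for s in self.shape))
        return fine.points


def _check_dims(psf: GaussianPSF, grid: SamplingGrid) -> None:
    if psf.dim != grid.dim:
        raise ValueError(
            f"PSF dimension {psf.dim} does not match grid dimension {grid.dim}"
        )


def psf_eval(psf: GaussianPSF, s: np.ndarray, x: np.ndarray) -> float:
    """Kernel value ``phi(s - x)`` at sample point ``s`` for a spike at ``x``."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    x = np.atleast_1d(np.asarray(x, dtype=float))
    z = (s - x) / psf.sigmas
    return psf.peak * float(np.exp(-0.5 * np.dot(z, z)))


def kernel_matrix(
    psf: GaussianPSF, points: np.ndarray, xs: np.ndarray
) -> np.ndarray:
    """Kernel values ``phi(t_j - x_i)`` as a (len(points), len(xs)) matrix."""
    xs = np.atleast_2d(np.asarray(xs, dtype=float))
    d2 = np.zeros((points.shape[0], xs.shape[0]))
    for k in range(xs.shape[1]):
        diff = (points[:, k, None] - xs[None, :, k]) / psf.sigmas[k]
        d2 += diff * diff
    return psf.peak * np.exp(-0.5 * d2)


def kernel_gradient(
    psf: GaussianPSF, points: np.ndarray, xs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel matrix and its spike-position gradient.

    Returns ``(K, dK)`` with ``K[j, i] = phi(t_j - x_i)`` and
    ``dK[j, i, k] = d phi(t_j - x_i) / d x_{i,k}
                  = K[j, i] * (t_{j,k} - x_{i,k}) / sigma_k^2``.
    """
    xs = np.atleast_2d(np.asarray(xs, dtype=float))
    K = kernel_matrix(psf, points, xs)
    dK = np.empty(K.shape + (xs.shape[1],))
    for k in range(xs.shape[1]):
        diff = points[:, k, None] - xs[None, :, k]
        dK[:, :, k] = K * diff / psf.sigmas[k] ** 2
    return K, dK


def forward(m: DiracMeasure, psf: GaussianPSF, grid: SamplingGrid) -> np.ndarray:
    """Blurred image of the measure on the grid, shape ``grid.shape``."""
    _check_dims(psf, grid)
    if m.N == 0:
        return np.zeros(grid.shape)
    if m.dim != grid.dim:
        raise ValueError("measure dimension does not match grid")
    K = kernel_matrix(psf, grid.points, m.positions)
    return (K @ m.amplitudes).reshape(grid.shape)


def adjoint_field(
    p: np.ndarray, psf: GaussianPSF, grid: SamplingGrid, x: np.ndarray
) -> float:
    """Quadrature value of ``(Phi* p)(x)`` at one continuous point."""
    return float(adjoint_field_batch(p, psf, grid, np.atleast_2d(x))[0])


def adjoint_field_batch(
    p: np.ndarray, psf: GaussianPSF, grid: SamplingGrid, xs: np.ndarray
) -> np.ndarray:
    """``(Phi* p)(x)`` for every row of ``xs``; empty input gives an empty vector."""
    _check_dims(psf, grid)
    xs = np.asarray(xs, dtype=float)
    if xs.size == 0:
        return np.zeros(0)
    xs = np.atleast_2d(xs)
    K = kernel_matrix(psf, grid.points, xs)
    return grid.pixel_measure * (np.ravel(p) @ K)
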