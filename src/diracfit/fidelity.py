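"""Data-fidelity terms, their gradients, and the dual certificate.

Two fidelities are supported, both evaluated against the acquisition ``y``
with an additive background ``b``:

* ``l2``:  f(w) = 1/2 ||w + b - y||^2_{L2(Omega)}   (Gaussian noise / BLASSO)
* ``kl``:  f(w) = D_KL(w + b, y)                    (Poisson noise)

where ``D_KL(s, t) = int s - t + t (log t - log s)`` extended by +inf when
``s`` is not positive, with the continuous-extension convention
``t log t = 0`` at ``t = 0`` (Poisson draws can produce zero-count pixels
even though the model assumes y > 0 almost everywhere; occurrences are
reported through the ``warn_zero_counts`` logger).

The dual certificate of the variational problem
``min_mu f(Phi mu) + lambda |mu|(Omega) (+ nonneg constraint)`` is

    eta(lambda, mu) = (1/lambda) * etat(mu),
    etat(mu) = -Phi* grad f(Phi mu)          (unconstrained, alpha = 0)
             = (-Phi* grad f(Phi mu))_+      (non-negative model, alpha = 1)

with the positive part taken *after* the adjoint.  Optimality of ``mu`` is
``||eta||_inf <= 1`` with ``eta = 1`` on the support.  The sup-norm over the
continuous domain is estimated by a dense-lattice scan followed by a bounded
local ascent from the best lattice point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import optimize

from .forward import GaussianPSF, SamplingGrid, forward, kernel_gradient, kernel_matrix
from .measures import DiracMeasure

__all__ = [
    "FidelitySpec",
    "CertificateField",
    "l2_fidelity",
    "kl_fidelity",
    "fidelity",
    "fidelity_gradient",
    "dual_certificate",
    "dual_variable",
    "kl_conjugate_1d",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FidelitySpec:
    """Which data term to use, the acquisition, the background, the constraint.

    Parameters
    ----------
    kind
        ``"l2"`` or ``"kl"``.
    y
        Acquisition image on the sampling grid (intensity units).
    b
        Scalar or image background; must be strictly positive for ``kl``.
    alpha
        1 activates the non-negativity constraint on the measure (the
        Poisson model); 0 is the plain signed BLASSO.
    """

    kind: str
    y: np.ndarray
    b: Union[float, np.ndarray]
    alpha: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("l2", "kl"):
            raise ValueError(f"unknown fidelity kind {self.kind!r}")
        if self.alpha not in (0, 1):
            raise ValueError("alpha must be 0 or 1")
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "y", y)
        if self.kind == "kl":
            if np.any(y < 0):
                raise ValueError("KL fidelity requires y >= 0")
            if np.any(np.asarray(self.b) <= 0):
                raise ValueError("KL fidelity requires b > 0 everywhere")
            n_zero = int(np.sum(y == 0))
            if n_zero:
                logger.info(
                    "KL acquisition has %d zero-count pixels; using t*log t = 0",
                    n_zero,
                )

    @property
    def background(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.b, dtype=float), self.y.shape)


def l2_fidelity(w: np.ndarray, spec: FidelitySpec, grid: SamplingGrid) -> float:
    """``1/2 * int (w + b - y)^2`` with the grid's midpoint quadrature."""
    r = np.asarray(w) + spec.background - spec.y
    return 0.5 * grid.pixel_measure * float(np.sum(r * r))


def kl_fidelity(w: np.ndarray, spec: FidelitySpec, grid: SamplingGrid) -> float:
    """Extended Kullback-Leibler divergence ``D_KL(w + b, y)``.

    Returns ``+inf`` when ``w + b`` is non-positive anywhere (the extension
    of the divergence off the positive cone); zero iff ``w + b = y``.
    """
    s = np.asarray(w) + spec.background
    if np.any(s <= 0):
        return np.inf
    y = spec.y
    with np.errstate(divide="ignore", invalid="ignore"):
        ylog = np.where(y > 0, y * (np.log(np.where(y > 0, y, 1.0)) - np.log(s)), 0.0)
    return grid.pixel_measure * float(np.sum(s - y + ylog))


def fidelity(w: np.ndarray, spec: FidelitySpec, grid: SamplingGrid) -> float:
    """Dispatch to the L2 or KL data term of ``spec``."""
    if spec.kind == "l2":
        return l2_fidelity(w, spec, grid)
    return kl_fidelity(w, spec, grid)


def fidelity_gradient(w: np.ndarray, spec: FidelitySpec) -> np.ndarray:
    """Gradient image of the data term in the quadrature-weighted inner product.

    L2: ``w + b - y``;  KL: ``1 - y / (w + b)`` (domain error if the KL
    argument is non-positive anywhere).
    """
    s = np.asarray(w) + spec.background
    if spec.kind == "l2":
        return s - spec.y
    if np.any(s <= 0):
        raise ValueError("KL gradient undefined: w + b <= 0 somewhere")
    return 1.0 - spec.y / s


@dataclass
class CertificateField:
    """The dual certificate ``eta(lambda, mu)`` as an evaluable field.

    Wraps the raw adjoint field ``g(x) = -(Phi* grad f)(x)`` together with
    ``lambda`` and the constraint flag; ``eta = g / lambda`` with a pointwise
    positive part when ``alpha = 1``.  ``eta`` is 1/lambda-homogeneous.
    """

    residual: np.ndarray  # flattened fidelity gradient on the grid
    lam: float
    alpha: int
    psf: GaussianPSF
    grid: SamplingGrid

    def raw(self, xs: np.ndarray) -> np.ndarray:
        """``g(x) / lambda`` without the positive part (signed field)."""
        xs = np.atleast_2d(np.asarray(xs, dtype=float))
        K = kernel_matrix(self.psf, self.grid.points, xs)
        g = -self.grid.pixel_measure * (self.residual @ K)
        return g / self.lam

    def __call__(self, xs: np.ndarray) -> np.ndarray:
        vals = self.raw(xs)
        if self.alpha == 1:
            vals = np.maximum(vals, 0.0)
        return vals

    def _raw_with_grad(self, x: np.ndarray, sign: float) -> tuple[float, np.ndarray]:
        K, dK = kernel_gradient(self.psf, self.grid.points, x[None, :])
        pm = self.grid.pixel_measure
        val = -pm * float(self.residual @ K[:, 0]) / self.lam
        grad = -pm * (self.residual @ dK[:, 0, :]) / self.lam
        return sign * val, sign * grad

    def argmax(
        self, refine: int = 4, local: bool = True
    ) -> tuple[np.ndarray, float]:
        """Maximiser of the certificate over ``Omega``.

        Scans a lattice ``refine`` times denser than the acquisition grid
        (ties broken by lowest flattened lattice index) and, optionally,
        polishes the best point by bounded local ascent.  For ``alpha = 0``
        the maximum of ``|eta|`` is located (sign tracked internally); for
        ``alpha = 1`` the field is already non-negative.
        """
        lattice = self.grid.refined_points(refine)
        vals = self.raw(lattice)
        score = np.abs(vals) if self.alpha == 0 else vals
        i = int(np.argmax(score))
        x0, v0 = lattice[i], float(score[i])
        sign = 1.0 if (self.alpha == 1 or vals[i] >= 0) else -1.0
        if local and v0 > 0:
            dom = self.grid.domain
            res = optimize.minimize(
                lambda x: tuple(-np.asarray(t) for t in self._raw_with_grad(x, sign)),
                x0,
                jac=True,
                bounds=list(zip(dom.lower, dom.upper)),
                method="L-BFGS-B",
                options={"maxiter": 40},
            )
            if np.isfinite(res.fun) and -res.fun > v0:
                x0, v0 = res.x, float(-res.fun)
        if self.alpha == 1:
            v0 = max(v0, 0.0)
        return np.atleast_1d(x0), v0

    def sup_norm(self, refine: int = 4, local: bool = True) -> float:
        """Estimate of ``||eta||_inf`` (``max eta`` when ``alpha = 1``)."""
        return self.argmax(refine=refine, local=local)[1]


def dual_certificate(
    m: DiracMeasure,
    lam: float,
    spec: FidelitySpec,
    psf: GaussianPSF,
    grid: SamplingGrid,
) -> CertificateField:
    """Certificate field ``eta(lambda, mu)`` for the current measure."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    w = forward(m, psf, grid)
    r = fidelity_gradient(w, spec)
    return CertificateField(np.ravel(r), float(lam), spec.alpha, psf, grid)


def dual_variable(
    m: DiracMeasure,
    lam: float,
    spec: FidelitySpec,
    psf: GaussianPSF,
    grid: SamplingGrid,
) -> np.ndarray:
    """Closed-form dual solution ``p = (y - Phi mu - b) / (lambda (Phi mu + b))``.

    Defined for the KL model; satisfies ``p > -1/lambda`` wherever ``y > 0``.
    """
    if spec.kind != "kl":
        raise ValueError("dual_variable is defined for the KL model")
    w = forward(m, psf, grid)
    s = w + spec.background
    if np.any(s <= 0):
        raise ValueError("Phi mu + b must be positive everywhere")
    return (spec.y - s) / (lam * s)


def kl_conjugate_1d(s_star: float, t: float, lam: float) -> float:
    """Convex conjugate of the scalar KL term ``g_t(s) = (s - t + t log(t/s))/lam``.

    ``g_t*(s*) = -(t/lam) log(1 - lam s*)`` for ``s* < 1/lam`` and ``+inf``
    otherwise; the supremum is attained at ``s = t / (1 - lam s*)``.
    Provided as an analytic oracle for tests of the Fenchel-Young inequality.
    """
    if t <= 0 or lam <= 0:
        raise ValueError("requires t > 0 and lambda > 0")
    if s_star >= 1.0 / lam:
        return np.inf
    return -(t / lam) * np.log1p(-lam * s_star)
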