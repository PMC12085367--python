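"""Sliding Frank-Wolfe: insertion, amplitude estimation, sliding, full solves."""

import itertools

import numpy as np
import pytest
from scipy import optimize as sopt

from diracfit import (
    DiracMeasure,
    FidelitySpec,
    dual_certificate,
    forward,
)
from diracfit.forward import kernel_matrix
from diracfit.sfw import (
    SFWConfig,
    amplitude_step,
    certificate_argmax,
    objective,
    sfw_solve,
    sliding_step,
)
from tests.conftest import make_noiseless_spec


def bruteforce_lasso(A, y, b, lam, pm, alpha):
    """Closed-form KKT enumeration for min 0.5*pm*||Aa+b-y||^2 + lam*||a||_1.

    Enumerates sign patterns (active sets for the non-negative case), solves
    the stationarity system on each, and returns the feasible candidate with
    the smallest objective.  Independent of the proximal solver under test.
    """
    n = A.shape[1]
    G = pm * (A.T @ A)
    c = pm * (A.T @ (y - b))

    def obj(a):
        r = A @ a + b - y
        return 0.5 * pm * float(r @ r) + lam * float(np.sum(np.abs(a)))

    best_a, best_val = np.zeros(n), obj(np.zeros(n))
    signs = [0, 1] if alpha else [-1, 0, 1]
    for pattern in itertools.product(signs, repeat=n):
        S = [i for i, s in enumerate(pattern) if s != 0]
        if not S:
            continue
        sv = np.array([pattern[i] for i in S], dtype=float)
        try:
            a_S = np.linalg.solve(G[np.ix_(S, S)], c[S] - lam * sv)
        except np.linalg.LinAlgError:
            continue
        if np.any(np.sign(a_S) != sv):
            continue
        a = np.zeros(n)
        a[S] = a_S
        val = obj(a)
        if val < best_val:
            best_a, best_val = a, val
    return best_a


def test_objective_zero_measure_and_indicator(psf1d, grid1d):
    y = np.full(64, 0.5)
    spec = FidelitySpec("kl", y, 0.1, alpha=1)
    m0 = DiracMeasure.empty(1)
    from diracfit import kl_fidelity

    assert objective(m0, 1.0, spec, psf1d, grid1d) == pytest.approx(
        kl_fidelity(np.zeros(64), spec, grid1d)
    )
    neg = DiracMeasure(np.array([[0.5]]), np.array([-1.0]))
    assert objective(neg, 1.0, spec, psf1d, grid1d) == np.inf


def test_certificate_argmax_finds_spike(psf1d, grid1d):
    x0 = 0.437
    spec = make_noiseless_spec(
        DiracMeasure(np.array([[x0]]), np.array([1.0])), psf1d, grid1d
    )
    cert = dual_certificate(DiracMeasure.empty(1), 0.5, spec, psf1d, grid1d)
    cfg = SFWConfig()
    x_star, val = certificate_argmax(cert, grid1d, cfg)
    assert abs(x_star[0] - x0) < 1.0 / (64 * cfg.lattice_refine)
    # returned value is at least the dense-lattice maximum
    lattice = grid1d.refined_points(cfg.lattice_refine)
    assert val >= np.max(cert(lattice)) - 1e-12


@pytest.mark.parametrize("alpha", [0, 1])
@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_amplitude_step_matches_bruteforce_l2(psf1d, grid1d, alpha, seed):
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0.1, 0.9, (3, 1))
    a_true = rng.uniform(0.5, 1.5, 3)
    b = 0.01
    y = forward(DiracMeasure(positions, a_true), psf1d, grid1d) + b
    y += rng.normal(0, 0.05, y.shape)
    spec = FidelitySpec("l2", y, b, alpha=alpha)
    lam = 0.05
    cfg = SFWConfig(amp_solver_iters=5000, amp_solver_tol=1e-11)
    a = amplitude_step(positions, lam, spec, psf1d, grid1d, cfg)
    A = kernel_matrix(psf1d, grid1d.points, positions)
    a_ref = bruteforce_lasso(A, y, b, lam, grid1d.pixel_measure, alpha)
    np.testing.assert_allclose(a, a_ref, atol=1e-6)


def test_amplitude_step_zero_above_threshold(psf1d, grid1d, noiseless_kl_spec):
    # lam at least the certificate sup of the zero measure: zero is optimal
    sup = dual_certificate(
        DiracMeasure.empty(1), 1.0, noiseless_kl_spec, psf1d, grid1d
    ).sup_norm()
    a = amplitude_step(
        np.array([[0.5]]), sup * 1.01, noiseless_kl_spec, psf1d, grid1d, SFWConfig()
    )
    np.testing.assert_allclose(a, 0.0, atol=1e-9)


def test_amplitude_step_nonnegative_under_constraint(psf1d, grid1d):
    rng = np.random.default_rng(5)
    y = rng.uniform(0.0, 0.2, 64)  # nearly pure background
    spec = FidelitySpec("kl", y, 0.1, alpha=1)
    a = amplitude_step(rng.uniform(0, 1, (4, 1)), 0.01, spec, psf1d, grid1d, SFWConfig())
    assert np.all(a >= 0)


def test_amplitude_step_noiseless_least_squares(psf1d, grid1d):
    # lam ~ 0, exact data, b=0: closed form a = <y, phi>/||phi||^2 = true amp
    m = DiracMeasure(np.array([[0.5]]), np.array([1.3]))
    y = forward(m, psf1d, grid1d)
    spec = FidelitySpec("l2", y, 0.0, alpha=0)
    a = amplitude_step(np.array([[0.5]]), 1e-10, spec, psf1d, grid1d, SFWConfig())
    assert a[0] == pytest.approx(1.3, abs=1e-6)


def test_amplitude_step_matches_generic_solver_kl(psf1d, grid1d):
    """Cross-check the proximal KL amplitude solve against an independent
    high-precision constrained optimiser on a 3-spike problem."""
    rng = np.random.default_rng(9)
    positions = np.array([[0.2], [0.5], [0.8]])
    b = 0.05
    y = forward(DiracMeasure(positions, np.array([1.0, 0.8, 1.2])), psf1d, grid1d) + b
    y = rng.poisson(200 * y) / 200.0
    spec = FidelitySpec("kl", y, b, alpha=1)
    lam = 0.02
    cfg = SFWConfig(amp_solver_iters=20000, amp_solver_tol=1e-12)
    a = amplitude_step(positions, lam, spec, psf1d, grid1d, cfg)
    A = kernel_matrix(psf1d, grid1d.points, positions)
    pm = grid1d.pixel_measure
    yf = np.ravel(y)

    def f(av):
        s = A @ av + b
        with np.errstate(divide="ignore"):
            ylog = np.where(yf > 0, yf * (np.log(np.where(yf > 0, yf, 1)) - np.log(s)), 0)
        return pm * float(np.sum(s - yf + ylog)) + lam * float(np.sum(av))

    ref = sopt.minimize(
        f, np.full(3, 0.5), bounds=[(0, None)] * 3, method="L-BFGS-B",
        options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 2000},
    )
    np.testing.assert_allclose(a, ref.x, atol=1e-6)


def test_sliding_improves_offset_spike(psf1d, grid1d):
    x_true = 0.5
    spec = make_noiseless_spec(
        DiracMeasure(np.array([[x_true]]), np.array([1.0])), psf1d, grid1d
    )
    offset = DiracMeasure(np.array([[x_true + 0.5 / 64]]), np.array([1.0]))
    out = sliding_step(offset, 0.001, spec, psf1d, grid1d, SFWConfig())
    assert abs(out.positions[0, 0] - x_true) < abs(offset.positions[0, 0] - x_true)
    assert objective(out, 0.001, spec, psf1d, grid1d) <= objective(
        offset, 0.001, spec, psf1d, grid1d
    )


def test_sliding_fixed_point_at_optimum(psf1d, grid1d, noiseless_kl_spec):
    lam = 1e-3
    res = sfw_solve(
        noiseless_kl_spec, psf1d, grid1d, lam,
        config=SFWConfig(max_iters=6, amp_after_sliding=True),
    )
    again = sliding_step(res.measure, lam, noiseless_kl_spec, psf1d, grid1d, SFWConfig())
    np.testing.assert_allclose(again.positions, res.measure.positions, atol=1e-5)


def test_sfw_returns_initialisation_when_lambda_large(psf1d, grid1d, noiseless_kl_spec):
    sup = dual_certificate(
        DiracMeasure.empty(1), 1.0, noiseless_kl_spec, psf1d, grid1d
    ).sup_norm()
    res = sfw_solve(noiseless_kl_spec, psf1d, grid1d, sup * 1.1)
    assert res.converged and res.n_iters == 0 and res.measure.N == 0


@pytest.mark.parametrize("kind,alpha,b", [("kl", 1, 0.01), ("l2", 0, 0.01)])
def test_sfw_noiseless_single_spike_recovery(psf1d, grid1d, kind, alpha, b):
    gt = DiracMeasure(np.array([[0.5]]), np.array([1.0]))
    spec = make_noiseless_spec(gt, psf1d, grid1d, kind=kind, b=b, alpha=alpha)
    lam = 0.01
    res = sfw_solve(
        spec, psf1d, grid1d, lam,
        config=SFWConfig(max_iters=8, amp_after_sliding=True, amp_solver_tol=1e-9),
    )
    m = res.measure
    assert res.converged and m.N == 1
    assert abs(m.positions[0, 0] - 0.5) < 1e-3
    assert abs(m.amplitudes[0] - 1.0) < 1e-2  # within the lambda-shrinkage bound
    # objective trace never increases
    diffs = np.diff(res.objective_trace)
    assert np.all(diffs <= 1e-9)


def test_sfw_objective_trace_monotone_on_noisy_data(psf1d, grid1d):
    rng = np.random.default_rng(12)
    gt = DiracMeasure(rng.uniform(0.1, 0.9, (4, 1)), rng.uniform(0.6, 1.4, 4))
    y = rng.poisson(100 * (forward(gt, psf1d, grid1d) + 0.01)) / 100.0
    spec = FidelitySpec("kl", y, 0.01, alpha=1)
    res = sfw_solve(spec, psf1d, grid1d, 0.05, config=SFWConfig(max_iters=10))
    assert np.all(np.diff(res.objective_trace) <= 1e-8)
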