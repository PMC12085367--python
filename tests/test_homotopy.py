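"""Homotopy loop: initialisation/update identities, residual targets, descent."""

import numpy as np
import pytest

from diracfit import (
    DiracMeasure,
    Domain,
    FidelitySpec,
    SamplingGrid,
    dual_certificate,
    estimate_background,
    forward,
    homotopy_solve,
    lambda_init,
    lambda_update,
    poisson_discrepancy_target,
    residual,
    sigma_target_masked,
    sigma_target_oracle,
)
from diracfit.homotopy import HomotopyConfig
from diracfit.sfw import SFWConfig
from diracfit.synthetic import background_mask, preset, simulate_acquisition
from tests.conftest import make_noiseless_spec


def poisson_spec(seed, kind="kl", scale_factor=4.0):
    scen = preset("sim1d", photon_scale=preset("sim1d").photon_scale * scale_factor)
    rng = np.random.default_rng([seed, 0])
    gt = DiracMeasure(rng.uniform(0.1, 0.9, (3, 1)), rng.uniform(0.8, 1.2, 3))
    y = simulate_acquisition(gt, scen, np.random.default_rng([seed, 1]))
    alpha = 1 if kind == "kl" else 0
    return gt, FidelitySpec(kind, y, scen.background, alpha=alpha), scen


def test_lambda_init_gives_inverse_gamma_certificate(psf1d, grid1d):
    gt, spec, scen = poisson_spec(0)
    m0 = DiracMeasure.empty(1)
    gamma = 0.9
    lam1 = lambda_init(m0, gamma, spec, psf1d, grid1d)
    sup = dual_certificate(m0, lam1, spec, psf1d, grid1d).sup_norm()
    assert sup == pytest.approx(1.0 / gamma, rel=1e-10)


def test_lambda_init_rejects_vanishing_certificate(psf1d, grid1d):
    y = np.full(64, 0.3)
    spec = FidelitySpec("kl", y, 0.3, alpha=1)  # y == b: nothing to explain
    with pytest.raises(ValueError):
        lambda_init(DiracMeasure.empty(1), 0.9, spec, psf1d, grid1d)


def test_lambda_update_formula_and_identity(psf1d, grid1d):
    assert lambda_update(2.0, 1.0, 1.0) == pytest.approx(1.0)
    gt, spec, scen = poisson_spec(1)
    m0 = DiracMeasure.empty(1)
    lam1 = lambda_init(m0, 0.9, spec, psf1d, grid1d)
    from diracfit import sfw_solve

    res = sfw_solve(spec, psf1d, grid1d, lam1, config=SFWConfig(max_iters=1))
    c = 40.0
    sup1 = dual_certificate(res.measure, lam1, spec, psf1d, grid1d).sup_norm()
    lam2 = lambda_update(lam1, sup1, c)
    assert lam2 < lam1
    sup2 = dual_certificate(res.measure, lam2, spec, psf1d, grid1d).sup_norm()
    assert sup2 == pytest.approx(1.0 + c, rel=1e-9)


def test_residual_delegates_to_fidelity(psf1d, grid1d, single_spike, noiseless_kl_spec):
    assert residual(single_spike, noiseless_kl_spec, psf1d, grid1d) == pytest.approx(
        0.0, abs=1e-13
    )
    from diracfit import kl_fidelity

    m0 = DiracMeasure.empty(1)
    assert residual(m0, noiseless_kl_spec, psf1d, grid1d) == kl_fidelity(
        np.zeros(64), noiseless_kl_spec, grid1d
    )


def test_sigma_target_oracle_scaling(psf1d, grid1d, single_spike, noiseless_kl_spec):
    assert sigma_target_oracle(
        single_spike, noiseless_kl_spec, psf1d, grid1d, inflation=1.5
    ) == pytest.approx(0.0, abs=1e-13)
    gt, spec, scen = poisson_spec(2)
    exact = residual(gt, spec, psf1d, grid1d)
    assert sigma_target_oracle(gt, spec, psf1d, grid1d, inflation=1.0) == pytest.approx(exact)
    assert sigma_target_oracle(gt, spec, psf1d, grid1d, inflation=1.5) == pytest.approx(1.5 * exact)


def test_sigma_target_masked_full_mask_equals_zero_measure_fidelity(grid1d):
    rng = np.random.default_rng(4)
    y = rng.uniform(0.1, 1.0, 64)
    b = 0.2
    from diracfit import kl_fidelity

    spec = FidelitySpec("kl", y, b, alpha=1)
    full = np.ones(64, dtype=bool)
    assert sigma_target_masked(y, full, b, "kl", grid1d) == pytest.approx(
        kl_fidelity(np.zeros(64), spec, grid1d)
    )
    # y == b on the mask: zero divergence
    yb = np.full(64, b)
    assert sigma_target_masked(yb, full, b, "kl", grid1d) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        sigma_target_masked(y, np.zeros(64, dtype=bool), b, "kl", grid1d)


def test_poisson_discrepancy_is_half_volume():
    g1 = SamplingGrid(Domain(np.array([0.0]), np.array([1.0])), (64,))
    g2 = SamplingGrid(Domain(np.zeros(2), np.ones(2)), (16, 16))
    assert poisson_discrepancy_target(g1) == pytest.approx(0.5)
    assert poisson_discrepancy_target(g2) == pytest.approx(0.5)


def test_estimate_background(grid1d):
    y = np.full(64, 0.5)
    mask = background_mask(grid1d, 0.2)
    assert estimate_background(y, mask, grid1d) == pytest.approx(0.5)
    one = np.zeros(64, dtype=bool)
    one[3] = True
    y2 = np.arange(64, dtype=float)
    assert estimate_background(y2, one, grid1d) == pytest.approx(3.0)


def test_homotopy_stops_immediately_when_target_met(psf1d, grid1d, noiseless_kl_spec):
    cfg = HomotopyConfig(sigma_target=1.0)  # zero-measure residual is below this? no:
    m0 = DiracMeasure.empty(1)
    r0 = residual(m0, noiseless_kl_spec, psf1d, grid1d)
    cfg = HomotopyConfig(sigma_target=r0 * 1.01)
    m, trace = homotopy_solve(noiseless_kl_spec, psf1d, grid1d, cfg, m0=m0)
    assert m.N == 0 and len(trace) == 0


@pytest.mark.parametrize("kind", ["kl", "l2"])
def test_homotopy_lambda_strictly_decreasing(psf1d, grid1d, kind):
    gt, spec, scen = poisson_spec(3, kind=kind)
    target = sigma_target_oracle(gt, spec, psf1d, grid1d)
    cfg = HomotopyConfig(c=10.0, max_outer=6, sigma_target=target)
    m, trace = homotopy_solve(spec, psf1d, grid1d, cfg)
    lams = np.array(trace.lam)
    assert np.all(np.diff(lams) < 0)


def test_homotopy_descent_and_tv_growth_tight_inner(psf1d, grid1d):
    """With accurate inner solves the residual path decreases strictly and
    the TV norm grows along the path."""
    gt, spec, scen = poisson_spec(7)
    inner = SFWConfig(max_iters=4, amp_after_sliding=True, amp_solver_tol=1e-9)
    cfg = HomotopyConfig(c=3.0, max_outer=5, sigma_target=0.0, inner=inner)
    m, trace = homotopy_solve(spec, psf1d, grid1d, cfg)
    sig = np.array(trace.sigma)
    tv = np.array([float(np.sum(np.abs(mm.amplitudes))) for mm in trace.measures])
    assert np.all(np.diff(sig) < 0)
    assert np.all(np.diff(tv) > -1e-9)


def test_warm_start_not_optimal_after_update(psf1d, grid1d):
    """Immediately after a lambda decrease the previous solution's certificate
    has sup-norm 1 + c, so the next inner solve must insert a spike."""
    gt, spec, scen = poisson_spec(8)
    c = 5.0
    cfg = HomotopyConfig(c=c, max_outer=4, sigma_target=0.0)
    m, trace = homotopy_solve(spec, psf1d, grid1d, cfg)
    assert len(trace) >= 2
    for t in range(len(trace) - 1):
        sup = dual_certificate(
            trace.measures[t], trace.lam[t + 1], spec, psf1d, grid1d
        ).sup_norm()
        assert sup == pytest.approx(1.0 + c, rel=1e-9)
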