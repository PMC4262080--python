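"""Transition kernels: symplecticity, reversibility, reductions, correctness."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import ks_2samp

from nrhmc import (
    AnalyticGaussianTarget,
    CallableTarget,
    SamplerConfig,
    generalized_leapfrog_trajectory,
    leapfrog_trajectory,
    run_chain,
    sample_target,
    smmala_transition,
    fixtures,
)
from nrhmc.diagnostics import integrated_autocorrelation


def _harmonic_grad(theta):
    return np.asarray(theta)  # U = theta^2 / 2


def test_leapfrog_single_step_hand_arithmetic():
    theta, eta = leapfrog_trajectory([1.0], [0.0], _harmonic_grad, eps=0.1, n_steps=1)
    assert theta[0] == pytest.approx(0.995, abs=1e-15)
    assert eta[0] == pytest.approx(-0.09975, abs=1e-15)


@given(
    eps=st.floats(0.01, 0.3),
    n_steps=st.integers(1, 40),
    omega=st.floats(0.3, 3.0),
    theta0=st.floats(-2, 2),
    eta0=st.floats(-2, 2),
)
def test_leapfrog_is_time_reversible(eps, n_steps, omega, theta0, eta0):
    grad = lambda th: omega**2 * np.asarray(th)
    th1, e1 = leapfrog_trajectory([theta0], [eta0], grad, eps, n_steps)
    th0, e0 = leapfrog_trajectory(th1, -np.asarray(e1), grad, eps, n_steps)
    assert abs(th0[0] - theta0) < 1e-10
    assert abs(e0[0] + eta0) < 1e-10


def test_leapfrog_step_jacobian_determinant_is_one():
    def step(z):
        t, e = leapfrog_trajectory([z[0]], [z[1]], _harmonic_grad, 0.15, 1)
        return np.array([t[0], e[0]])

    z0 = np.array([0.4, -0.7])
    h = 1e-6
    J = np.empty((2, 2))
    for i in range(2):
        zp, zm = z0.copy(), z0.copy()
        zp[i] += h
        zm[i] -= h
        J[:, i] = (step(zp) - step(zm)) / (2 * h)
    assert np.linalg.det(J) == pytest.approx(1.0, abs=1e-8)


def test_hamiltonian_error_scales_quadratically_in_eps():
    def max_dH(eps, n):
        h0 = 0.5  # H at (theta, eta) = (1, 0)
        worst = 0.0
        th, eta = np.array([1.0]), np.array([0.0])
        for _ in range(n):
            th, eta = leapfrog_trajectory(th, eta, _harmonic_grad, eps, 1)
            worst = max(worst, abs(0.5 * (th[0] ** 2 + eta[0] ** 2) - h0))
        return worst

    ratio = max_dH(0.2, 40) / max_dH(0.1, 80)
    assert 3.0 < ratio < 5.0


def test_generalized_leapfrog_reduces_to_leapfrog_for_constant_metric():
    cov = np.array([[1.0, 0.6], [0.6, 1.5]])
    tgt = AnalyticGaussianTarget([0.0, 0.0], cov)
    prec = tgt.precision
    theta0 = np.array([0.7, -0.4])
    eta0 = np.array([0.5, 0.2])
    th_g, eta_g, _ = generalized_leapfrog_trajectory(
        theta0, eta0, lambda th, order: tgt.evaluate(th, order), eps=0.1, n_steps=12,
        fp_tol=1e-14, fp_max=30,
    )
    th_l, eta_l = leapfrog_trajectory(
        theta0, eta0, lambda th: prec @ th, eps=0.1, n_steps=12, mass_inv=cov
    )
    assert np.allclose(th_g, th_l, atol=1e-12)
    assert np.allclose(eta_g, eta_l, atol=1e-12)


def test_generalized_leapfrog_reversible_on_mapk(mapk_posterior):
    theta0 = fixtures.theta_true("mapk_erk")
    eta0 = np.array([0.3, -0.4])
    geom = lambda th, order: mapk_posterior.evaluate(th, order=order)
    th1, e1, _ = generalized_leapfrog_trajectory(
        theta0, eta0, geom, eps=0.2, n_steps=10, fp_tol=1e-10, fp_max=50
    )
    th0, e0, _ = generalized_leapfrog_trajectory(
        th1, -e1, geom, eps=0.2, n_steps=10, fp_tol=1e-10, fp_max=50
    )
    assert np.max(np.abs(th0 - theta0)) < 1e-8
    assert np.max(np.abs(e0 + eta0)) < 1e-8


def test_rmhmc_equals_hmc_with_constant_mass():
    """With a constant metric the RMHMC kernel reduces exactly to HMC whose
    mass matrix is that metric (same seed, same draws, same chain)."""
    cov = np.array([[1.0, 0.9], [0.9, 2.0]])
    tgt = AnalyticGaussianTarget([1.0, -2.0], cov)
    prec = np.linalg.inv(cov)
    common = dict(eps=0.4, n_steps=6, n_samples=400, burn_in=50, seed=9)
    ch_h = sample_target(tgt, SamplerConfig(algorithm="hmc", mass=prec, **common))
    ch_r = sample_target(tgt, SamplerConfig(algorithm="rmhmc", fp_tol=1e-13, fp_max=40, **common))
    assert np.allclose(ch_h.thetas, ch_r.thetas, atol=1e-9)
    assert np.array_equal(ch_h.accepted, ch_r.accepted)


def test_same_seed_gives_bitwise_identical_chains(mapk_model, mapk_dataset, mapk_prior):
    cfg = SamplerConfig(algorithm="smmala", backend="newton", eps=1.0, n_samples=150, burn_in=20, seed=31)
    a = run_chain(mapk_model, mapk_dataset, mapk_prior, cfg)
    b = run_chain(mapk_model, mapk_dataset, mapk_prior, cfg)
    assert np.array_equal(a.thetas, b.thetas)
    assert np.array_equal(a.loglik, b.loglik)
    assert np.array_equal(a.delta_h, b.delta_h)


def test_recorded_loglik_matches_reevaluation(mapk_model, mapk_dataset, mapk_prior, mapk_posterior):
    cfg = SamplerConfig(algorithm="smmala", backend="newton", eps=1.0, n_samples=50, burn_in=10, seed=3)
    ch = run_chain(mapk_model, mapk_dataset, mapk_prior, cfg)
    for k in (0, 17, 49):
        ev = mapk_posterior.evaluate(ch.thetas[k], order=0)
        assert ch.loglik[k] == pytest.approx(ev.loglik, abs=1e-7)


def test_empty_chain_after_burn_in():
    tgt = AnalyticGaussianTarget([0.0], [[1.0]])
    cfg = SamplerConfig(algorithm="hmc", eps=0.3, n_steps=5, n_samples=0, burn_in=10, seed=0)
    ch = sample_target(tgt, cfg)
    assert len(ch) == 0
    assert ch.t_elapsed == 0.0


def test_zero_delta_h_always_accepts():
    # flat potential: the Hamiltonian is exactly conserved, dH = 0, accept prob 1
    tgt = CallableTarget(logpost=lambda th: 0.0, grad=lambda th: np.zeros_like(th), dim=1)
    cfg = SamplerConfig(algorithm="hmc", eps=0.2, n_steps=5, n_samples=100, burn_in=0, seed=1)
    ch = sample_target(tgt, cfg)
    assert ch.acceptance_rate == 1.0
    assert np.allclose(ch.delta_h, 0.0, atol=1e-12)


def test_minus_infinity_proposals_are_rejected():
    # a hard wall just above the start: every trajectory that crosses fails
    def logpost(th):
        return -np.inf if np.abs(th[0]) > 0.05 else 0.0

    tgt = CallableTarget(logpost=logpost, grad=lambda th: np.zeros_like(th), dim=1)
    cfg = SamplerConfig(
        algorithm="hmc", eps=1.0, n_steps=10, n_samples=60, burn_in=0, seed=2, jitter=0.0
    )
    with pytest.raises(RuntimeError, match="consecutive"):
        # every proposal fails -> the early-abort guard fires with advice
        sample_target(tgt, cfg)


def test_smmala_isotropic_proposal_and_closed_form_ratio():
    """For a 1-D Gaussian target the SMMALA acceptance ratio has a closed form;
    the kernel must reproduce it exactly."""
    s2 = 1.7**2
    tgt = AnalyticGaussianTarget([0.0], [[s2]])
    eps = 0.8
    theta = np.array([1.3])
    cur = tgt.evaluate(theta, order=1)
    rng = np.random.default_rng(77)
    cfg = SamplerConfig(algorithm="smmala", eps=eps, n_samples=1, seed=0)
    new, rec = smmala_transition(cur, tgt, cfg, rng)
    # replicate the proposal draw with the same generator state
    rng2 = np.random.default_rng(77)
    z = rng2.standard_normal(1)
    a = 1.0 - eps**2 / 2.0
    prop = a * theta[0] + eps * np.sqrt(s2) * z[0]
    logpi = lambda x: -x**2 / (2 * s2)
    logq = lambda x_from, x_to: -((x_to - a * x_from) ** 2) / (2 * eps**2 * s2)
    expected = logpi(prop) + logq(prop, theta[0]) - logpi(theta[0]) - logq(theta[0], prop)
    assert rec["delta_h"] == pytest.approx(-expected, abs=1e-12)


def test_smmala_zero_gradient_identity_metric_is_isotropic_random_walk():
    tgt = CallableTarget(
        logpost=lambda th: 0.0,
        grad=lambda th: np.zeros_like(th),
        metric=lambda th: np.eye(2),
        dim=2,
    )
    eps = 0.5
    cur = tgt.evaluate(np.array([0.2, -0.1]), order=1)
    rng = np.random.default_rng(5)
    cfg = SamplerConfig(algorithm="smmala", eps=eps, n_samples=1, seed=0)
    new, rec = smmala_transition(cur, tgt, cfg, rng)
    rng2 = np.random.default_rng(5)
    z = rng2.standard_normal(2)
    assert np.allclose(new.theta, cur.theta + eps * z, atol=1e-14)
    assert rec["accepted"]  # flat target, symmetric proposal: always accepted


@pytest.mark.parametrize("algorithm,eps,n_steps", [
    ("hmc", 1.0, 10),
    ("rmhmc", 1.0, 6),
    ("smmala", 1.5, 1),
])
def test_detailed_balance_flux_on_binned_gaussian(algorithm, eps, n_steps):
    """Empirical transition flux between bins of a 1-D Gaussian is symmetric
    within Monte-Carlo error for every kernel."""
    tgt = AnalyticGaussianTarget([0.0], [[1.0]])
    cfg = SamplerConfig(
        algorithm=algorithm, eps=eps, n_steps=n_steps, n_samples=6000, burn_in=500, seed=13
    )
    ch = sample_target(tgt, cfg)
    edges = [-0.6, 0.0, 0.6]
    bins = np.digitize(ch.thetas[:, 0], edges)
    flux = np.zeros((4, 4))
    for a, b in zip(bins[:-1], bins[1:]):
        flux[a, b] += 1
    for i in range(4):
        for j in range(i + 1, 4):
            tot = flux[i, j] + flux[j, i]
            if tot < 20:
                continue
            assert abs(flux[i, j] - flux[j, i]) < 5.0 * np.sqrt(tot)


def test_cross_sampler_agreement_on_mapk(mapk_model, mapk_dataset, mapk_prior):
    """RMHMC and HMC marginals on the MAPK posterior are statistically
    indistinguishable (two-sample KS on tau-thinned samples)."""
    ch_h = run_chain(
        mapk_model, mapk_dataset, mapk_prior,
        SamplerConfig(algorithm="hmc", backend="newton", eps=0.2, n_steps=20,
                      n_samples=1200, burn_in=200, seed=4),
    )
    ch_r = run_chain(
        mapk_model, mapk_dataset, mapk_prior,
        SamplerConfig(algorithm="rmhmc", backend="newton", eps=0.18, n_steps=8,
                      n_samples=1200, burn_in=200, seed=5, fp_max=20),
    )
    assert ch_h.acceptance_rate > 0.8  # tuned eps: very high but < 100%
    assert ch_h.acceptance_rate < 1.0
    for k in range(2):
        tau = max(
            integrated_autocorrelation(ch_h.thetas[:, k]).tau_int,
            integrated_autocorrelation(ch_r.thetas[:, k]).tau_int,
        )
        thin = max(1, int(np.ceil(2 * tau)))
        p = ks_2samp(ch_h.thetas[::thin, k], ch_r.thetas[::thin, k]).pvalue
        assert p > 0.01


def test_chain_io_roundtrip(tmp_path, mapk_model, mapk_dataset, mapk_prior):
    from nrhmc import load_chain, save_chain

    cfg = SamplerConfig(algorithm="smmala", backend="newton", eps=1.0, n_samples=40, burn_in=5, seed=8)
    ch = run_chain(mapk_model, mapk_dataset, mapk_prior, cfg)
    path = tmp_path / "chain.tsv"
    save_chain(ch, path)
    back = load_chain(path)
    assert np.allclose(back.thetas, ch.thetas)
    assert np.array_equal(back.accepted, ch.accepted)
    assert back.config.algorithm == "smmala"
    assert back.t_elapsed == pytest.approx(ch.t_elapsed)


def test_tune_epsilon_reaches_target_window():
    from nrhmc import tune_epsilon

    tgt = AnalyticGaussianTarget([0.0, 0.0], np.eye(2))
    cfg = SamplerConfig(algorithm="hmc", eps=5.0, n_steps=10, n_samples=100, seed=6)
    eps = tune_epsilon(tgt, cfg, accept_range=(0.8, 0.95), pilot_samples=150)
    assert eps < 5.0
    ch = sample_target(
        tgt, SamplerConfig(algorithm="hmc", eps=eps, n_steps=10, n_samples=400, burn_in=50, seed=6)
    )
    assert 0.7 <= ch.acceptance_rate <= 1.0


def test_config_validation():
    with pytest.raises(ValueError):
        SamplerConfig(algorithm="nuts")
    with pytest.raises(ValueError):
        SamplerConfig(eps=-0.1)
    with pytest.raises(ValueError):
        SamplerConfig(backend="magic")
    cfg = SamplerConfig(n_samples=1000)
    assert cfg.burn_in == 100  # default 10%
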