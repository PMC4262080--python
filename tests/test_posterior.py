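"""Likelihood, gradient, Fisher metric and metric derivatives."""

import numpy as np
import pytest

from nrhmc import (
    Dataset,
    Experiment,
    GaussianPrior,
    SteadyStatePosterior,
    build_model,
    fisher_metric,
    log_likelihood,
    log_posterior_gradient,
    metric_derivatives,
    read_dataset,
    solve_steady_state,
    write_dataset,
    fixtures,
)


def test_log_likelihood_matches_naive_loop(mapk_model, mapk_dataset):
    theta = fixtures.theta_true("mapk_erk")
    states = [
        solve_steady_state(mapk_model, theta, e.u, order=0).xbar for e in mapk_dataset
    ]
    L = log_likelihood(mapk_model, mapk_dataset, states)
    # independent brute-force summation over every (i, j) term
    L_ref = 0.0
    for e, x in zip(mapk_dataset, states):
        h = mapk_model.output(x)[e.observables]
        for yij, hij, sij in zip(e.y, h, e.sigma):
            L_ref += -0.5 * ((yij - hij) / sij) ** 2 - np.log(sij * np.sqrt(2 * np.pi))
    assert L == pytest.approx(L_ref, rel=1e-12)


def test_log_likelihood_normalisation_only_at_zero_residual(toy_model):
    ds = Dataset([Experiment(u=[1.0], observables=[0], y=[1.0], sigma=[0.5])])
    L = log_likelihood(toy_model, ds, [np.array([1.0])])
    assert L == pytest.approx(-np.log(0.5 * np.sqrt(2 * np.pi)))


def test_single_residual_of_one_sigma_contributes_minus_half(toy_model):
    sigma = 0.3
    ds = Dataset([Experiment(u=[1.0], observables=[0], y=[1.0 + sigma], sigma=[sigma])])
    L = log_likelihood(toy_model, ds, [np.array([1.0])])
    assert L == pytest.approx(-0.5 - np.log(sigma * np.sqrt(2 * np.pi)))


def test_missing_steady_state_gives_minus_infinity(toy_model):
    ds = Dataset([Experiment(u=[1.0], observables=[0], y=[1.0], sigma=[0.5])])
    assert log_likelihood(toy_model, ds, [None]) == -np.inf


def test_gradient_is_prior_only_when_sensitivities_vanish():
    prior = GaussianPrior.vague(3)
    theta = np.array([0.5, -1.0, 2.0])
    CS = [np.zeros((2, 3))]
    g = log_posterior_gradient(CS, [np.array([0.1, 0.2])], [np.array([1.0, 1.0])], prior, theta)
    assert np.allclose(g, -prior.precision @ theta)
    # at the prior mean with zero residuals the gradient vanishes entirely
    g0 = log_posterior_gradient(CS, [np.zeros(2)], [np.ones(2)], prior, prior.mean)
    assert np.allclose(g0, 0.0)


def test_gradient_matches_finite_differences_on_mma(mma_model, mma_dataset, mma_prior):
    post = SteadyStatePosterior(mma_model, mma_dataset, mma_prior, backend="newton")
    rng = np.random.default_rng(7)
    theta = fixtures.theta_true("insulin_mma") + rng.uniform(-0.3, 0.3, 6)
    ev = post.evaluate(theta, order=1)
    h = 1e-6
    for r in range(6):
        tp, tm = theta.copy(), theta.copy()
        tp[r] += h
        tm[r] -= h
        fd = (post.evaluate(tp, order=0).logpost - post.evaluate(tm, order=0).logpost) / (2 * h)
        assert ev.grad[r] == pytest.approx(fd, rel=1e-5, abs=1e-8)


def test_fisher_metric_reduces_to_prior_precision():
    prior = GaussianPrior.vague(2)
    G = fisher_metric([np.zeros((1, 2))], [np.ones(1)], prior.precision)
    assert np.allclose(G, prior.precision)


def test_fisher_metric_scalar_closed_form():
    # one observation, CS = a: G = a^2/sigma^2 + 1/xi
    a, sigma, xi = 1.7, 0.4, 4.0
    G = fisher_metric([np.array([[a]])], [np.array([sigma])], np.array([[1 / xi]]))
    assert G[0, 0] == pytest.approx(a**2 / sigma**2 + 1 / xi)


def test_metric_positive_definite_across_prior_draws(mma_model, mma_dataset, mma_prior):
    post = SteadyStatePosterior(mma_model, mma_dataset, mma_prior, backend="newton")
    rng = np.random.default_rng(123)
    for _ in range(50):
        theta = mma_prior.sample(rng)
        ev = post.evaluate(theta, order=1)
        if not ev.ok:
            continue
        assert np.min(np.linalg.eigvalsh(ev.G)) > 0.0


def test_metric_derivatives_vanish_for_theta_independent_steady_state():
    # dx/dt = k (u - x): xbar = u for every parameter value, so S = 0 and
    # the metric is the constant prior precision with zero derivatives
    model = build_model(
        """
[states]
x
[parameters]
k
[ode]
k*(drive - x)
[output_matrix]
1
[initial_condition]
0
[inputs]
drive
"""
    )
    ds = Dataset([Experiment(u=[1.0], observables=[0], y=[1.0], sigma=[0.2])])
    prior = GaussianPrior.vague(1)
    post = SteadyStatePosterior(model, ds, prior, backend="newton")
    ev = post.evaluate(np.array([0.3]), order=2)
    assert np.allclose(ev.G, prior.precision, atol=1e-12)
    assert np.allclose(ev.dG, 0.0, atol=1e-10)


def test_metric_derivative_closed_form_on_linear_toy(toy_model):
    # G(theta) = u^2 e^{-2 theta} / sigma^2 + 1/xi, dG/dtheta = -2 u^2 e^{-2 theta}/sigma^2
    u, sigma, xi, theta = 2.0, 0.5, 4.0, 0.4
    ds = Dataset([Experiment(u=[u], observables=[0], y=[1.0], sigma=[sigma])])
    prior = GaussianPrior(mean=[0.0], cov=[[xi]])
    post = SteadyStatePosterior(toy_model, ds, prior, backend="newton")
    ev = post.evaluate(np.array([theta]), order=2)
    expect_G = u**2 * np.exp(-2 * theta) / sigma**2 + 1 / xi
    expect_dG = -2 * u**2 * np.exp(-2 * theta) / sigma**2
    assert ev.G[0, 0] == pytest.approx(expect_G, rel=1e-9)
    assert ev.dG[0, 0, 0] == pytest.approx(expect_dG, rel=1e-7)


def test_metric_derivatives_match_finite_differences(mapk_posterior):
    theta = fixtures.theta_true("mapk_erk")
    ev = mapk_posterior.evaluate(theta, order=2)
    h = 1e-5
    for k in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        fd = (mapk_posterior.evaluate(tp, order=1).G - mapk_posterior.evaluate(tm, order=1).G) / (2 * h)
        assert np.max(np.abs(ev.dG[k] - fd)) / np.max(np.abs(fd)) < 1e-4


def test_gauss_newton_consistency_at_truth(mapk_model):
    """With noise-free data and a vague prior, the likelihood gradient is ~0 at
    the true parameters and the metric's data term equals the Gauss-Newton
    Hessian of -L."""
    design = fixtures.mapk_design(seed=0)
    design.sigma = 0.2
    ds = fixtures.generate_dataset(mapk_model, design)
    for e in ds.experiments:  # strip the noise: replace y by the recorded truth
        e.y = e.y_true.copy()
    prior = GaussianPrior.vague(2, variance=1e6)
    # very tight steady-state tolerance so the FD of the gradient is clean
    post = SteadyStatePosterior(mapk_model, ds, prior, backend="newton", newton_tol=1e-14)
    tt = fixtures.theta_true("mapk_erk")
    ev = post.evaluate(tt, order=1)
    grad_L = ev.grad - prior.grad_logpdf(tt)
    assert np.max(np.abs(grad_L)) < 1e-6
    # FD of the analytic gradient gives the Hessian of -L to high accuracy
    h = 1e-4
    H = np.empty((2, 2))
    for r in range(2):
        tp, tm = tt.copy(), tt.copy()
        tp[r] += h
        tm[r] -= h
        gp = post.evaluate(tp, order=1).grad - prior.grad_logpdf(tp)
        gm = post.evaluate(tm, order=1).grad - prior.grad_logpdf(tm)
        H[:, r] = -(gp - gm) / (2 * h)
    G_data = ev.G - prior.precision
    assert np.max(np.abs(G_data - H)) / np.max(np.abs(H)) < 1e-8


def test_dataset_roundtrip(tmp_path, mapk_dataset):
    path = tmp_path / "data.tsv"
    write_dataset(mapk_dataset, path)
    back = read_dataset(path)
    assert len(back) == len(mapk_dataset)
    for a, b in zip(back, mapk_dataset):
        assert np.allclose(a.u, b.u)
        assert np.allclose(a.y, b.y)
        assert np.allclose(a.sigma, b.sigma)
        assert np.array_equal(a.observables, b.observables)


def test_dataset_validation_errors(mapk_model):
    with pytest.raises(ValueError, match="non-negative"):
        Experiment(u=[1.0], observables=[0], y=[1.0], sigma=[-0.1])
    ds = Dataset([Experiment(u=[1.0, 2.0], observables=[0], y=[1.0], sigma=[0.1])])
    with pytest.raises(ValueError, match="inputs"):
        ds.validate_against(mapk_model)
    ds2 = Dataset([Experiment(u=[1.0], observables=[5], y=[1.0], sigma=[0.1])])
    with pytest.raises(ValueError, match="observable"):
        ds2.validate_against(mapk_model)
    ds3 = Dataset([Experiment(u=[1.0], observables=[0], y=[1.0], sigma=[0.0])])
    with pytest.raises(ValueError, match="positive sigma"):
        ds3.validate_against(mapk_model)


def test_backend_evaluations_agree(mapk_model, mapk_dataset, mapk_prior):
    theta = fixtures.theta_true("mapk_erk") + 0.1
    nr = SteadyStatePosterior(mapk_model, mapk_dataset, mapk_prior, backend="newton")
    it = SteadyStatePosterior(mapk_model, mapk_dataset, mapk_prior, backend="integration")
    ev_n, ev_i = nr.evaluate(theta, order=2), it.evaluate(theta, order=2)
    assert ev_n.loglik == pytest.approx(ev_i.loglik, abs=1e-6)
    assert np.allclose(ev_n.grad, ev_i.grad, atol=1e-5)
    assert np.allclose(ev_n.G, ev_i.G, rtol=1e-5, atol=1e-7)


def test_newton_backend_falls_back_and_recovers(mapk_model, mapk_dataset, mapk_prior):
    """A huge parameter jump invalidates the sensitivity prediction; the
    backend must fall back to integration and still return a valid geometry."""
    post = SteadyStatePosterior(mapk_model, mapk_dataset, mapk_prior, backend="newton")
    tt = fixtures.theta_true("mapk_erk")
    post.evaluate(tt, order=1)
    far = tt + np.array([6.0, -6.0])
    ev = post.evaluate(far, order=1)
    assert ev.ok
    ref = SteadyStatePosterior(
        mapk_model, mapk_dataset, mapk_prior, backend="integration"
    ).evaluate(far, order=1)
    assert ev.loglik == pytest.approx(ref.loglik, abs=1e-5)
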