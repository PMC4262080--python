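"""Gaussian-error posterior over log-parameters and its Riemannian geometry.

For steady-state perturbation data ``y_ij`` (observable ``i``, experiment ``j``
with input ``u_j`` and known noise scale ``sigma_ij``) the log-likelihood is

    L(theta) = -1/2 sum_ij [ (y_ij - h_i(xbar_j))^2 / sigma_ij^2
                             + log(2 pi sigma_ij^2) ]

with ``h = C xbar + c0``.  Together with a Gaussian prior N(mu, Xi) on theta
this yields, from first-order steady-state sensitivities ``S_j`` alone,

* the log-posterior gradient
      grad = sum_j (C S_j)^T diag(sigma_j)^-2 r_j  -  Xi^-1 (theta - mu),
* the expected-Fisher-information metric tensor
      G(theta) = sum_j (C S_j)^T diag(sigma_j)^-2 (C S_j)  +  Xi^-1,

which is symmetric positive definite because of the prior term.  The metric
derivatives dG/dtheta_k needed by Riemannian samplers follow from the
second-order sensitivities by the product rule.  Normalisation constants of
likelihood and prior are retained in the logged scalar values (so they are
comparable across noise settings) but cancel in every acceptance ratio; the
model evidence is never evaluated.

:class:`SteadyStatePosterior` bundles all of this behind one ``evaluate``
call with two interchangeable steady-state backends:

* ``"integration"`` — every evaluation integrates the IVP from ``x0``
  (the baseline samplers);
* ``"newton"`` — steady states are tracked across parameter moves: a
  first-order prediction from the previous point seeds a Newton-Raphson
  refinement, falling back to integration when Newton fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .model import ODEModel
from .steady_state import (
    SteadyStateError,
    SteadyStateResult,
    newton_refine,
    second_order_rhs,
    solve_by_integration,
)

__all__ = [
    "Experiment",
    "Dataset",
    "GaussianPrior",
    "GeometryEvaluation",
    "SteadyStatePosterior",
    "AnalyticGaussianTarget",
    "CallableTarget",
    "log_likelihood",
    "log_posterior_gradient",
    "fisher_metric",
    "metric_derivatives",
    "read_dataset",
    "write_dataset",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------


@dataclass
class Experiment:
    """One steady-state perturbation experiment."""

    u: np.ndarray  # input vector
    observables: np.ndarray  # 0-based indices into the rows of C
    y: np.ndarray
    sigma: np.ndarray
    y_true: np.ndarray | None = None  # noise-free outputs (synthetic data only)

    def __post_init__(self):
        self.u = np.atleast_1d(np.asarray(self.u, dtype=float))
        self.observables = np.atleast_1d(np.asarray(self.observables, dtype=int))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if not (len(self.observables) == len(self.y) == len(self.sigma)):
            raise ValueError("observables, y and sigma must have equal length")
        # sigma == 0 is tolerated for noise-free oracle datasets; inference
        # (SteadyStatePosterior) insists on strictly positive noise scales
        if np.any(self.sigma < 0):
            raise ValueError("noise scales sigma must be non-negative")


@dataclass
class Dataset:
    """A steady-state perturbation dataset: one :class:`Experiment` per input."""

    experiments: list[Experiment]
    input_names: tuple[str, ...] | None = None

    def __len__(self):
        return len(self.experiments)

    def __iter__(self):
        return iter(self.experiments)

    @property
    def n_observations(self) -> int:
        return sum(len(e.y) for e in self.experiments)

    def validate_against(self, model: ODEModel) -> None:
        n_out = model.output_matrix.shape[0]
        for k, e in enumerate(self.experiments):
            if e.u.shape != (model.n_inputs,):
                raise ValueError(f"experiment {k + 1}: expected {model.n_inputs} inputs")
            if np.any(e.observables < 0) or np.any(e.observables >= n_out):
                raise ValueError(f"experiment {k + 1}: observable index out of range")
            if np.any(e.sigma <= 0):
                raise ValueError(
                    f"experiment {k + 1}: inference requires strictly positive sigma"
                )


def read_dataset(path, input_names=None) -> Dataset:
    """Read the delimited-text dataset format.

    Columns: ``experiment`` (1-based id), one column per input, ``observable``
    (1-based row index into C), ``value``, ``sigma``.  Header row required.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    fixed = {"experiment", "observable", "value", "sigma"}
    missing = fixed - set(df.columns)
    if missing:
        raise ValueError(f"dataset file missing columns: {sorted(missing)}")
    in_cols = [c for c in df.columns if c not in fixed]
    if input_names is not None:
        in_cols = list(input_names)
    experiments = []
    for _, grp in df.groupby("experiment", sort=True):
        u = grp[in_cols].iloc[0].to_numpy(dtype=float)
        experiments.append(
            Experiment(
                u=u,
                observables=grp["observable"].to_numpy(dtype=int) - 1,
                y=grp["value"].to_numpy(dtype=float),
                sigma=grp["sigma"].to_numpy(dtype=float),
            )
        )
    return Dataset(experiments=experiments, input_names=tuple(in_cols))


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset in the delimited-text format used by :func:`read_dataset`."""
    names = dataset.input_names or tuple(
        f"u{i + 1}" for i in range(len(dataset.experiments[0].u))
    )
    rows = []
    for j, e in enumerate(dataset.experiments, start=1):
        for i in range(len(e.y)):
            row = {"experiment": j}
            row.update({nm: e.u[k] for k, nm in enumerate(names)})
            row["observable"] = int(e.observables[i]) + 1
            row["value"] = e.y[i]
            row["sigma"] = e.sigma[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class GaussianPrior:
    """Gaussian prior N(mu, Xi) on the log-parameters theta."""

    mean: np.ndarray
    cov: np.ndarray
    precision: np.ndarray = field(init=False, repr=False)
    _chol: np.ndarray = field(init=False, repr=False)
    _log_norm: float = field(init=False, repr=False)

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        m = len(self.mean)
        if self.cov.shape != (m, m):
            raise ValueError("prior covariance shape mismatch")
        self._chol = np.linalg.cholesky(self.cov)
        self.precision = sla.cho_solve((self._chol, True), np.eye(m))
        self._log_norm = -0.5 * (
            m * np.log(2.0 * np.pi) + 2.0 * np.sum(np.log(np.diag(self._chol)))
        )

    @classmethod
    def vague(cls, m: int, variance: float = 4.0, mean=None) -> "GaussianPrior":
        """A weak prior covering several orders of magnitude of each rate.

        The default variance of 4 log-units gives a +/- 2-sigma range of about
        e^-4 .. e^4, i.e. roughly 3.5 orders of magnitude around the mean.
        """
        mean = np.zeros(m) if mean is None else np.asarray(mean, dtype=float)
        return cls(mean=mean, cov=variance * np.eye(m))

    def logpdf(self, theta) -> float:
        d = np.asarray(theta, dtype=float) - self.mean
        return float(self._log_norm - 0.5 * d @ self.precision @ d)

    def grad_logpdf(self, theta) -> np.ndarray:
        return -self.precision @ (np.asarray(theta, dtype=float) - self.mean)

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        z = rng.standard_normal((size or 1, len(self.mean)))
        draws = self.mean + z @ self._chol.T
        return draws if size else draws[0]


# --------------------------------------------------------------------------
# assembly of likelihood, gradient, metric
# --------------------------------------------------------------------------


def log_likelihood(model: ODEModel, dataset: Dataset, steady_states) -> float:
    """Gaussian log-likelihood (normalisation constants included).

    ``steady_states`` is one steady-state vector (or
    :class:`~nrhmc.steady_state.SteadyStateResult`) per experiment.  A missing
    steady state (``None``) yields ``-inf``.
    """
    L = 0.0
    for e, ss in zip(dataset.experiments, steady_states):
        if ss is None:
            logger.debug("missing steady state -> log-likelihood = -inf")
            return -np.inf
        x = ss.xbar if isinstance(ss, SteadyStateResult) else np.asarray(ss, dtype=float)
        h = model.output(x)[e.observables]
        r = e.y - h
        L += float(
            -0.5 * np.sum((r / e.sigma) ** 2)
            - np.sum(np.log(e.sigma))
            - 0.5 * len(r) * np.log(2.0 * np.pi)
        )
    return L


def log_posterior_gradient(CS_list, residuals, sigmas, prior: GaussianPrior, theta) -> np.ndarray:
    """Gradient of log-likelihood + log-prior from output sensitivities.

    ``CS_list[j] = C_j S_j`` maps parameter space to observed outputs of
    experiment ``j``; ``residuals[j] = y_j - h_j``.
    """
    g = prior.grad_logpdf(theta)
    for CS, r, s in zip(CS_list, residuals, sigmas):
        g = g + CS.T @ (r / s**2)
    return g


def fisher_metric(CS_list, sigmas, prior_precision) -> np.ndarray:
    """Expected Fisher information plus prior precision (always SPD)."""
    G = np.array(prior_precision, dtype=float, copy=True)
    for CS, s in zip(CS_list, sigmas):
        W = CS / (s**2)[:, None]
        G += CS.T @ W
    return 0.5 * (G + G.T)


def metric_derivatives(CS_list, CS2_list, sigmas) -> np.ndarray:
    """Slabs ``dG/dtheta_k`` (k leading) from first/second-order sensitivities.

    The prior precision is constant and contributes nothing; each slab is
    symmetric by construction.
    """
    m = CS_list[0].shape[1]
    dG = np.zeros((m, m, m))
    for CS, CS2, s in zip(CS_list, CS2_list, sigmas):
        w = 1.0 / s**2
        # CS2[i, r, k] = d(CS[i, r])/dtheta_k
        A = np.einsum("irk,i,is->krs", CS2, w, CS)
        dG += A + np.swapaxes(A, 1, 2)
    return dG


# --------------------------------------------------------------------------
# geometry evaluation
# --------------------------------------------------------------------------


@dataclass
class GeometryEvaluation:
    """Everything the samplers need at one point theta."""

    theta: np.ndarray
    ok: bool
    loglik: float = -np.inf
    logprior: float = -np.inf
    logpost: float = -np.inf
    grad: np.ndarray | None = None
    G: np.ndarray | None = None
    dG: np.ndarray | None = None
    steady_states: list | None = None
    error: str | None = None
    _chol: np.ndarray | None = field(default=None, repr=False)

    def chol_G(self) -> np.ndarray:
        """Lower Cholesky factor of the metric (cached)."""
        if self._chol is None:
            self._chol = np.linalg.cholesky(self.G)
        return self._chol

    def logdet_G(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self.chol_G()))))

    def solve_G(self, b) -> np.ndarray:
        return sla.cho_solve((self.chol_G(), True), b)


class _Target:
    """Minimal protocol shared by posteriors and analytic test targets."""

    dim: int

    def initial_point(self) -> np.ndarray:
        raise NotImplementedError

    def evaluate(self, theta, order: int = 1) -> GeometryEvaluation:
        raise NotImplementedError


class SteadyStatePosterior(_Target):
    """Posterior geometry of a steady-state ODE model given perturbation data.

    ``order`` in :meth:`evaluate` selects how much geometry is computed:
    0 — log-posterior only; 1 — plus gradient and metric ``G`` (first-order
    sensitivities); 2 — plus metric derivatives (second-order sensitivities).

    The ``newton`` backend is stateful: it remembers the last successfully
    evaluated point (the *anchor*) and predicts the next steady states from it
    with the first-order sensitivity before Newton refinement.  Failures fall
    back to integration from ``x0``; if that also fails the evaluation reports
    ``ok=False`` with ``logpost=-inf`` and the proposal is rejected upstream.
    """

    def __init__(
        self,
        model: ODEModel,
        dataset: Dataset,
        prior: GaussianPrior,
        backend: str = "newton",
        newton_tol: float | None = None,
        newton_max_iter: int = 20,
        integration_tol: float = 1e-8,
        t_max: float = 1e7,
        integration_rtol: float = 1e-8,
        integration_atol: float = 1e-10,
    ):
        if backend not in ("newton", "integration"):
            raise ValueError(f"unknown backend {backend!r}")
        dataset.validate_against(model)
        self.model = model
        self.dataset = dataset
        self.prior = prior
        self.backend = backend
        self.newton_tol = newton_tol
        self.newton_max_iter = newton_max_iter
        self.integration_tol = integration_tol
        self.t_max = t_max
        self.integration_rtol = integration_rtol
        self.integration_atol = integration_atol

        self.U = np.stack([e.u for e in dataset.experiments])
        self.fallback_count = 0
        self.failure_count = 0
        self.n_evaluations = 0
        self._anchor = None  # (theta, X, S) of last successful evaluation

    @property
    def dim(self) -> int:
        return self.model.n_parameters

    def initial_point(self) -> np.ndarray:
        return self.prior.mean.copy()

    def reset_anchor(self) -> None:
        self._anchor = None

    # -- steady-state backends --------------------------------------------

    def _integrate_all(self, theta) -> np.ndarray:
        """Steady states for all experiments, integrating one stacked system."""
        model, U = self.model, self.U
        nE, n = U.shape[0], model.n_states
        x0 = np.tile(model.initial_condition, nE)

        def rhs(t, z):
            return model.f(z.reshape(nE, n), theta, U).ravel()

        def jac(t, z):
            J = model.f_x(z.reshape(nE, n), theta, U)
            return sla.block_diag(*J)

        from .steady_state import _integrate_to_steady_state

        z = _integrate_to_steady_state(
            rhs,
            jac,
            x0,
            self.integration_tol,
            self.t_max,
            self.integration_rtol,
            self.integration_atol,
        )
        return z.reshape(nE, n)

    def _integrate_one(self, theta, j) -> np.ndarray:
        return solve_by_integration(
            self.model,
            theta,
            self.U[j],
            convergence_tol=self.integration_tol,
            t_max=self.t_max,
            rtol=self.integration_rtol,
            atol=self.integration_atol,
        )

    def _newton_all(self, theta, X_guess) -> tuple[np.ndarray, np.ndarray]:
        """Batched Newton over experiments; returns (X, converged mask)."""
        model, U = self.model, self.U
        nE, n = X_guess.shape
        X = X_guess.copy()
        converged = np.zeros(nE, dtype=bool)
        prev_res = np.full(nE, np.inf)
        grow = np.zeros(nE, dtype=int)
        failed = np.zeros(nE, dtype=bool)
        for _ in range(self.newton_max_iter + 1):
            F, J, _ = model.first_bundle(X, theta, U)
            finite = np.isfinite(F).all(axis=1) & np.isfinite(J).all(axis=(1, 2))
            failed |= ~finite
            res = np.where(finite, np.max(np.abs(np.where(finite[:, None], F, 0.0)), axis=1), np.inf)
            if self.newton_tol is None:
                limit = 1e-9 * (1.0 + np.max(np.abs(X), axis=1))
            else:
                limit = np.full(nE, self.newton_tol)
            converged = (res <= limit) & finite
            grow = np.where(res > prev_res, grow + 1, 0)
            failed |= grow >= 3
            active = ~(converged | failed)
            if not active.any():
                break
            prev_res = res
            idx_active = np.flatnonzero(active)
            try:
                X[idx_active] -= np.linalg.solve(J[idx_active], F[idx_active][..., None])[..., 0]
            except np.linalg.LinAlgError:
                # at least one singular Jacobian in the batch: fall back row-wise
                for idx in idx_active:
                    try:
                        X[idx] -= np.linalg.solve(J[idx], F[idx])
                    except np.linalg.LinAlgError:
                        failed[idx] = True
        # reject converged states with clearly negative concentrations
        neg = converged & (X.min(axis=1) < -1e-9)
        converged &= ~neg
        return X, converged

    def _steady_states(self, theta) -> tuple[np.ndarray, list[SteadyStateResult]]:
        nE, n = self.U.shape[0], self.model.n_states
        if self.backend == "integration" or self._anchor is None:
            X = self._integrate_all(theta)
            if self.backend == "newton":
                # polish and pick up convergence bookkeeping per experiment
                X2, conv = self._newton_all(theta, X)
                X = np.where(conv[:, None], X2, X)
            F = self.model.first_bundle(X, theta, self.U)[0]
            res = np.max(np.abs(F), axis=1)
            results = [
                SteadyStateResult(xbar=X[j], residual_norm=float(res[j]), method="integration")
                for j in range(nE)
            ]
            return X, results

        theta_a, X_a, S_a = self._anchor
        X_guess = X_a + S_a @ (np.asarray(theta) - theta_a)
        X, conv = self._newton_all(theta, X_guess)
        results: list[SteadyStateResult] = []
        for j in range(nE):
            if conv[j]:
                f = self.model.f(X[j], theta, self.U[j])
                results.append(
                    SteadyStateResult(
                        xbar=X[j], residual_norm=float(np.max(np.abs(f))), method="newton"
                    )
                )
                continue
            # Newton failed for this experiment: fall back to integration
            self.fallback_count += 1
            logger.debug("Newton fallback for experiment %d at theta=%s", j + 1, theta)
            x = self._integrate_one(theta, j)
            ref = newton_refine(
                self.model, theta, self.U[j], x, tol=self.newton_tol, max_iter=self.newton_max_iter
            )
            X[j] = ref.xbar
            results.append(ref)
        return X, results

    # -- public API ---------------------------------------------------------

    def evaluate(self, theta, order: int = 1) -> GeometryEvaluation:
        theta = np.asarray(theta, dtype=float)
        self.n_evaluations += 1
        try:
            X, ss_results = self._steady_states(theta)
        except SteadyStateError as exc:
            self.failure_count += 1
            logger.debug("steady-state failure at theta=%s: %s", theta, exc)
            return GeometryEvaluation(theta=theta, ok=False, error=str(exc))

        model, ds = self.model, self.dataset
        logprior = self.prior.logpdf(theta)
        loglik = log_likelihood(model, ds, list(X))
        ev = GeometryEvaluation(
            theta=theta,
            ok=True,
            loglik=loglik,
            logprior=logprior,
            logpost=loglik + logprior,
            steady_states=ss_results,
        )
        if order < 1 and self.backend != "newton":
            # the newton backend always computes S: it feeds the next anchor
            return ev

        try:
            F, J, Fth = model.first_bundle(X, theta, self.U)
            S = np.linalg.solve(J, -Fth)  # batched (nE, n, m)
        except np.linalg.LinAlgError:
            self.failure_count += 1
            return GeometryEvaluation(theta=theta, ok=False, error="singular Jacobian")
        if not np.all(np.isfinite(S)):
            self.failure_count += 1
            return GeometryEvaluation(theta=theta, ok=False, error="non-finite sensitivities")

        C, c0 = model.output_matrix, model.output_offset
        CS_list, residuals, sigmas = [], [], []
        for j, e in enumerate(ds.experiments):
            CS_list.append(C[e.observables] @ S[j])
            residuals.append(e.y - (C[e.observables] @ X[j] + c0[e.observables]))
            sigmas.append(e.sigma)
        ev.grad = log_posterior_gradient(CS_list, residuals, sigmas, self.prior, theta)
        ev.G = fisher_metric(CS_list, sigmas, self.prior.precision)

        if order >= 2:
            fxx, fxth, fthth = model.second_bundle(X, theta, self.U)
            rhs = np.stack(
                [second_order_rhs(fxx[j], fxth[j], fthth[j], S[j]) for j in range(len(ds))]
            )
            n, m = model.n_states, model.n_parameters
            S2 = np.linalg.solve(J, rhs.reshape(len(ds), n, m * m)).reshape(len(ds), n, m, m)
            S2 = 0.5 * (S2 + np.swapaxes(S2, 2, 3))
            CS2_list = [
                np.einsum("oi,irk->ork", C[e.observables], S2[j])
                for j, e in enumerate(ds.experiments)
            ]
            ev.dG = metric_derivatives(CS_list, CS2_list, sigmas)
            for j, r in enumerate(ev.steady_states):
                r.S, r.S2 = S[j], S2[j]
        else:
            for j, r in enumerate(ev.steady_states):
                r.S = S[j]

        # successful full evaluation becomes the new Newton anchor
        if self.backend == "newton":
            self._anchor = (theta.copy(), X.copy(), S.copy())
        return ev


# --------------------------------------------------------------------------
# analytic targets (used by sampler tests and the tuning utilities)
# --------------------------------------------------------------------------


class AnalyticGaussianTarget(_Target):
    """A multivariate Gaussian with its exact (constant) Fisher metric."""

    def __init__(self, mean, cov):
        self.mean = np.atleast_1d(np.asarray(mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(cov, dtype=float))
        self.dim = len(self.mean)
        self._chol = np.linalg.cholesky(self.cov)
        self.precision = sla.cho_solve((self._chol, True), np.eye(self.dim))
        self._log_norm = -0.5 * (
            self.dim * np.log(2 * np.pi) + 2 * np.sum(np.log(np.diag(self._chol)))
        )
        self._dG = np.zeros((self.dim,) * 3)

    def initial_point(self) -> np.ndarray:
        return self.mean.copy()

    def evaluate(self, theta, order: int = 1) -> GeometryEvaluation:
        theta = np.asarray(theta, dtype=float)
        d = theta - self.mean
        lp = float(self._log_norm - 0.5 * d @ self.precision @ d)
        return GeometryEvaluation(
            theta=theta,
            ok=True,
            loglik=lp,
            logprior=0.0,
            logpost=lp,
            grad=-self.precision @ d,
            G=self.precision.copy(),
            dG=self._dG,
        )


class CallableTarget(_Target):
    """Wrap plain callables (logpost, grad, optional metric) as a target."""

    def __init__(self, logpost, grad, metric=None, dmetric=None, dim=1, x0=None):
        self._logpost = logpost
        self._grad = grad
        self._metric = metric
        self._dmetric = dmetric
        self.dim = dim
        self._x0 = np.zeros(dim) if x0 is None else np.asarray(x0, dtype=float)

    def initial_point(self) -> np.ndarray:
        return self._x0.copy()

    def evaluate(self, theta, order: int = 1) -> GeometryEvaluation:
        theta = np.asarray(theta, dtype=float)
        lp = float(self._logpost(theta))
        G = None
        dG = None
        if self._metric is not None:
            G = np.atleast_2d(np.asarray(self._metric(theta), dtype=float))
            dG = (
                np.zeros((self.dim,) * 3)
                if self._dmetric is None
                else np.asarray(self._dmetric(theta), dtype=float)
            )
        return GeometryEvaluation(
            theta=theta,
            ok=np.isfinite(lp),
            loglik=lp,
            logprior=0.0,
            logpost=lp,
            grad=np.atleast_1d(np.asarray(self._grad(theta), dtype=float)),
            G=G,
            dG=dG,
        )
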