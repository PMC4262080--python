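"""Markov transition kernels: HMC, RMHMC and SMMALA, with a chain runner.

Each kernel comes in two steady-state backends selected through
:class:`~nrhmc.posterior.SteadyStatePosterior` — ``integration`` (the baseline:
every geometry evaluation integrates the initial value problem) and ``newton``
(steady states tracked by sensitivity-seeded Newton-Raphson).  The kernels
themselves are backend-agnostic: they only see ``target.evaluate``.

Kernels
-------
* HMC — Euclidean Hamiltonian dynamics with mass matrix ``M`` (identity by
  default), integrated by the explicit (kick-drift-kick) leapfrog, Metropolis
  acceptance on the Hamiltonian error.
* RMHMC — position-specific momentum covariance ``G(theta)`` (expected Fisher
  information + prior precision); the equations of motion are implicit and are
  integrated by the generalised leapfrog with fixed-point iterations.
* SMMALA — one-step preconditioned Langevin proposal
  ``N(theta + eps^2/2 G^-1 grad, eps^2 G^-1)`` with the asymmetric
  Metropolis-Hastings correction.

Any backend failure (steady state unreachable, singular Jacobian, fixed point
not converging) aborts the proposal, which is rejected — Metropolis
correctness is preserved because the rejected move never depends on partial
information.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .posterior import (
    Dataset,
    GaussianPrior,
    GeometryEvaluation,
    SteadyStatePosterior,
)

__all__ = [
    "SamplerConfig",
    "Chain",
    "TrajectoryError",
    "leapfrog_trajectory",
    "generalized_leapfrog_trajectory",
    "hmc_transition",
    "rmhmc_transition",
    "smmala_transition",
    "sample_target",
    "run_chain",
    "tune_epsilon",
    "save_chain",
    "load_chain",
]

logger = logging.getLogger(__name__)

_ORDER = {"hmc": 1, "smmala": 1, "rmhmc": 2}


class TrajectoryError(RuntimeError):
    """A Hamiltonian trajectory could not be completed; the proposal is rejected."""


@dataclass
class SamplerConfig:
    """Fully determines a sampling run given model + data (reproducibility).

    ``eps`` is the integrator step size, ``n_steps`` the leapfrog steps per
    trajectory (ignored by SMMALA), ``jitter`` the +/- fraction of uniform
    trajectory-length jitter (0 disables it), ``fp_tol``/``fp_max`` control the
    generalised-leapfrog fixed-point iterations, and ``mass`` is the HMC mass
    matrix (identity when ``None``).
    """

    algorithm: str = "hmc"
    backend: str = "newton"
    eps: float = 0.1
    n_steps: int = 20
    n_samples: int = 1000
    burn_in: int | None = None
    seed: int = 0
    fp_tol: float = 1e-8
    fp_max: int = 10
    mass: np.ndarray | None = None
    jitter: float = 0.2
    theta0: np.ndarray | None = None

    def __post_init__(self):
        if self.algorithm not in _ORDER:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.backend not in ("newton", "integration"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if not self.eps > 0:
            raise ValueError("eps must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if self.burn_in is None:
            self.burn_in = self.n_samples // 10
        if self.mass is not None:
            self.mass = np.atleast_2d(np.asarray(self.mass, dtype=float))

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["mass"] is not None:
            d["mass"] = np.asarray(d["mass"]).tolist()
        if d["theta0"] is not None:
            d["theta0"] = np.asarray(d["theta0"]).tolist()
        return d


@dataclass
class Chain:
    """An ordered posterior sample with per-transition records."""

    thetas: np.ndarray  # (N, m)
    loglik: np.ndarray
    logpost: np.ndarray
    accepted: np.ndarray
    delta_h: np.ndarray
    fallbacks: np.ndarray
    t_elapsed: float
    config: SamplerConfig
    parameter_names: tuple[str, ...] | None = None

    def __len__(self):
        return self.thetas.shape[0]

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted)) if len(self) else np.nan

    def to_dataframe(self) -> pd.DataFrame:
        names = self.parameter_names or tuple(
            f"theta_{i + 1}" for i in range(self.thetas.shape[1])
        )
        df = pd.DataFrame(self.thetas, columns=list(names))
        df["loglik"] = self.loglik
        df["logpost"] = self.logpost
        df["accepted"] = self.accepted.astype(int)
        df["delta_h"] = self.delta_h
        df["fallbacks"] = self.fallbacks
        return df


def save_chain(chain: Chain, path) -> None:
    """Write a chain as delimited text with a ``#``-prefixed metadata header."""
    meta = {
        "config": chain.config.to_dict(),
        "t_elapsed": chain.t_elapsed,
        "parameter_names": chain.parameter_names,
    }
    with open(path, "w") as fh:
        fh.write("# nrhmc chain\n")
        fh.write("# " + json.dumps(meta) + "\n")
        chain.to_dataframe().to_csv(fh, sep="\t", index=False)


def load_chain(path) -> Chain:
    meta = None
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, ln in enumerate(lines):
        if ln.startswith("#"):
            stripped = ln[1:].strip()
            if stripped.startswith("{"):
                meta = json.loads(stripped)
        else:
            body_start = i
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    cfg_d = meta["config"]
    cfg = SamplerConfig(**cfg_d)
    names = meta.get("parameter_names")
    theta_cols = [c for c in df.columns if c not in ("loglik", "logpost", "accepted", "delta_h", "fallbacks")]
    return Chain(
        thetas=df[theta_cols].to_numpy(dtype=float),
        loglik=df["loglik"].to_numpy(dtype=float),
        logpost=df["logpost"].to_numpy(dtype=float),
        accepted=df["accepted"].to_numpy(dtype=bool),
        delta_h=df["delta_h"].to_numpy(dtype=float),
        fallbacks=df["fallbacks"].to_numpy(dtype=int),
        t_elapsed=float(meta["t_elapsed"]),
        config=cfg,
        parameter_names=tuple(names) if names else None,
    )


# --------------------------------------------------------------------------
# integrators
# --------------------------------------------------------------------------


def leapfrog_trajectory(theta0, eta0, grad_potential, eps, n_steps, mass_inv=None):
    """Explicit kick-drift-kick leapfrog for ``H = U(theta) + 1/2 eta' M^-1 eta``.

    ``grad_potential`` returns the gradient of the potential ``U`` (i.e. of the
    *negative* log-posterior).  The map is exactly time-reversible and volume
    preserving.  Non-finite gradients raise :class:`TrajectoryError`.
    """
    theta = np.atleast_1d(np.asarray(theta0, dtype=float)).copy()
    eta = np.atleast_1d(np.asarray(eta0, dtype=float)).copy()

    def gradU(th):
        g = np.atleast_1d(np.asarray(grad_potential(th), dtype=float))
        if not np.all(np.isfinite(g)):
            raise TrajectoryError("non-finite gradient mid-trajectory")
        return g

    def vel(p):
        return p if mass_inv is None else mass_inv @ p

    eta = eta - 0.5 * eps * gradU(theta)
    for i in range(n_steps):
        theta = theta + eps * vel(eta)
        g = gradU(theta)
        if i < n_steps - 1:
            eta = eta - eps * g
    eta = eta - 0.5 * eps * g
    return theta, eta


def _dH_dtheta(ev: GeometryEvaluation, eta: np.ndarray) -> np.ndarray:
    """Position derivative of the Riemannian Hamiltonian.

    dH/dtheta_k = -d(logpost)/dtheta_k + 1/2 tr(G^-1 dG_k)
                  - 1/2 (G^-1 eta)' dG_k (G^-1 eta)
    """
    Ginv_eta = ev.solve_G(eta)
    m = len(eta)
    out = -ev.grad.copy()
    if ev.dG is not None and np.any(ev.dG):
        Ginv = ev.solve_G(np.eye(m))
        out += 0.5 * np.einsum("ij,kji->k", Ginv, ev.dG)
        out -= 0.5 * np.einsum("i,kij,j->k", Ginv_eta, ev.dG, Ginv_eta)
    return out


def generalized_leapfrog_trajectory(
    theta0, eta0, geom_fn, eps, n_steps, fp_tol=1e-8, fp_max=10, geom0=None
):
    """Generalised (implicit) leapfrog for the Riemannian Hamiltonian.

    ``geom_fn(theta, order)`` must return a
    :class:`~nrhmc.posterior.GeometryEvaluation`; ``order=1`` evaluations carry
    the metric only and are used inside the implicit drift, ``order=2``
    evaluations (with metric derivatives) anchor the half-kicks.  Fixed-point
    non-convergence within ``fp_max`` iterations raises
    :class:`TrajectoryError` and the caller rejects the proposal.

    Returns ``(theta, eta, geometry_at_endpoint)``.
    """
    theta = np.atleast_1d(np.asarray(theta0, dtype=float)).copy()
    eta = np.atleast_1d(np.asarray(eta0, dtype=float)).copy()
    g2 = geom0 if geom0 is not None else geom_fn(theta, 2)
    if not g2.ok:
        raise TrajectoryError("geometry evaluation failed at trajectory start")

    for _ in range(n_steps):
        # implicit half kick on the momentum
        eta_h = eta.copy()
        for _ in range(fp_max):
            eta_new = eta - 0.5 * eps * _dH_dtheta(g2, eta_h)
            delta = np.max(np.abs(eta_new - eta_h))
            eta_h = eta_new
            if delta < fp_tol:
                break
        else:
            raise TrajectoryError("momentum fixed point did not converge")

        # implicit drift on the position
        v0 = g2.solve_G(eta_h)
        theta_new = theta + eps * v0
        g_mid = None
        for _ in range(fp_max):
            g_mid = geom_fn(theta_new, 1)
            if not g_mid.ok:
                raise TrajectoryError("geometry evaluation failed during drift")
            cand = theta + 0.5 * eps * (v0 + g_mid.solve_G(eta_h))
            delta = np.max(np.abs(cand - theta_new))
            theta_new = cand
            if delta < fp_tol:
                break
        else:
            raise TrajectoryError("position fixed point did not converge")

        g2 = geom_fn(theta_new, 2)
        if not g2.ok:
            raise TrajectoryError("geometry evaluation failed after drift")
        # explicit half kick
        eta = eta_h - 0.5 * eps * _dH_dtheta(g2, eta_h)
        theta = theta_new

    return theta, eta, g2


# --------------------------------------------------------------------------
# transition kernels
# --------------------------------------------------------------------------


def _jittered_steps(config: SamplerConfig, rng: np.random.Generator) -> int:
    if config.jitter <= 0:
        return config.n_steps
    factor = rng.uniform(1.0 - config.jitter, 1.0 + config.jitter)
    return max(1, int(round(config.n_steps * factor)))


def hmc_transition(cur: GeometryEvaluation, target, config: SamplerConfig, rng):
    """One Euclidean HMC transition; returns ``(new_state, record)``."""
    m = len(cur.theta)
    if config.mass is None:
        eta0 = rng.standard_normal(m)
        kin0 = 0.5 * eta0 @ eta0
        mass_inv = None
    else:
        L = np.linalg.cholesky(config.mass)
        eta0 = L @ rng.standard_normal(m)
        mass_inv = sla.cho_solve((L, True), np.eye(m))
        kin0 = 0.5 * eta0 @ mass_inv @ eta0
    n_steps = _jittered_steps(config, rng)
    h0 = -cur.logpost + kin0

    fall0 = getattr(target, "fallback_count", 0)
    try:
        ev, eta = _leapfrog_on_target(target, cur, eta0, config.eps, n_steps, mass_inv)
    except TrajectoryError as exc:
        logger.debug("HMC trajectory aborted: %s", exc)
        rec = _record(cur, accepted=False, delta_h=np.inf, fallbacks=getattr(target, "fallback_count", 0) - fall0)
        rng.uniform()  # keep the draw sequence aligned with accepted paths
        return cur, rec
    kin1 = 0.5 * (eta @ eta if mass_inv is None else eta @ mass_inv @ eta)
    h1 = -ev.logpost + kin1
    dh = h1 - h0
    accept = np.log(rng.uniform()) < -dh
    new = ev if accept else cur
    return new, _record(new, accepted=bool(accept), delta_h=float(dh), fallbacks=getattr(target, "fallback_count", 0) - fall0)


def _leapfrog_on_target(target, cur, eta0, eps, n_steps, mass_inv):
    """Leapfrog with one geometry evaluation per step, returning the endpoint."""
    theta = cur.theta.copy()
    eta = eta0 - 0.5 * eps * (-cur.grad)
    ev = cur
    for i in range(n_steps):
        v = eta if mass_inv is None else mass_inv @ eta
        theta = theta + eps * v
        ev = target.evaluate(theta, order=1)
        if not ev.ok or not np.all(np.isfinite(ev.grad)):
            raise TrajectoryError(ev.error or "non-finite gradient")
        if i < n_steps - 1:
            eta = eta + eps * ev.grad
    eta = eta + 0.5 * eps * ev.grad
    return ev, eta


def rmhmc_transition(cur: GeometryEvaluation, target, config: SamplerConfig, rng):
    """One Riemannian-manifold HMC transition.

    Momentum is drawn from N(0, G(theta)); the proposal integrates the implicit
    Hamiltonian flow with the generalised leapfrog; acceptance uses the full
    position-dependent Hamiltonian including the 1/2 log det G term.
    """
    m = len(cur.theta)
    eta0 = cur.chol_G() @ rng.standard_normal(m)
    h0 = -cur.logpost + 0.5 * cur.logdet_G() + 0.5 * eta0 @ cur.solve_G(eta0)
    n_steps = _jittered_steps(config, rng)
    fall0 = getattr(target, "fallback_count", 0)
    try:
        theta1, eta1, ev = generalized_leapfrog_trajectory(
            cur.theta,
            eta0,
            lambda th, order: target.evaluate(th, order=order),
            config.eps,
            n_steps,
            fp_tol=config.fp_tol,
            fp_max=config.fp_max,
            geom0=cur,
        )
    except TrajectoryError as exc:
        logger.debug("RMHMC trajectory aborted: %s", exc)
        rng.uniform()
        return cur, _record(cur, accepted=False, delta_h=np.inf, fallbacks=getattr(target, "fallback_count", 0) - fall0)
    h1 = -ev.logpost + 0.5 * ev.logdet_G() + 0.5 * eta1 @ ev.solve_G(eta1)
    dh = h1 - h0
    accept = np.log(rng.uniform()) < -dh
    new = ev if accept else cur
    return new, _record(new, accepted=bool(accept), delta_h=float(dh), fallbacks=getattr(target, "fallback_count", 0) - fall0)


def smmala_transition(cur: GeometryEvaluation, target, config: SamplerConfig, rng):
    """One simplified-manifold MALA transition.

    Proposal: ``N(theta + eps^2/2 G^-1 grad, eps^2 G^-1)`` with the standard
    Metropolis-Hastings correction for the position-dependent, asymmetric
    proposal.  ``delta_h`` records the negative log acceptance ratio.
    """
    m = len(cur.theta)
    eps = config.eps
    mu_fwd = cur.theta + 0.5 * eps**2 * cur.solve_G(cur.grad)
    z = rng.standard_normal(m)
    prop_theta = mu_fwd + eps * sla.solve_triangular(cur.chol_G().T, z, lower=False)

    fall0 = getattr(target, "fallback_count", 0)
    ev = target.evaluate(prop_theta, order=1)
    fallbacks = getattr(target, "fallback_count", 0) - fall0
    if not ev.ok:
        rng.uniform()
        return cur, _record(cur, accepted=False, delta_h=np.inf, fallbacks=fallbacks)

    def logq(ev_from, x_to):
        mu = ev_from.theta + 0.5 * eps**2 * ev_from.solve_G(ev_from.grad)
        d = x_to - mu
        return float(
            0.5 * ev_from.logdet_G() - m * np.log(eps) - 0.5 * d @ ev_from.G @ d / eps**2
        )

    log_ratio = ev.logpost + logq(ev, cur.theta) - cur.logpost - logq(cur, prop_theta)
    accept = np.log(rng.uniform()) < log_ratio
    new = ev if accept else cur
    return new, _record(new, accepted=bool(accept), delta_h=float(-log_ratio), fallbacks=fallbacks)


def _record(ev: GeometryEvaluation, accepted: bool, delta_h: float, fallbacks: int):
    return {
        "theta": ev.theta,
        "loglik": ev.loglik,
        "logpost": ev.logpost,
        "accepted": accepted,
        "delta_h": delta_h,
        "fallbacks": fallbacks,
    }


_KERNELS = {"hmc": hmc_transition, "rmhmc": rmhmc_transition, "smmala": smmala_transition}


# --------------------------------------------------------------------------
# chain runner
# --------------------------------------------------------------------------


def sample_target(target, config: SamplerConfig, parameter_names=None) -> Chain:
    """Run a Markov chain on any geometry target; identical seeds give identical chains.

    All stochastic draws flow through one seeded generator owned by the chain.
    Aborts with tuning advice if the backend fails for 25 consecutive proposals
    within the first 50 transitions.
    """
    rng = np.random.default_rng(config.seed)
    kernel = _KERNELS[config.algorithm]
    order = _ORDER[config.algorithm]

    theta = (
        np.asarray(config.theta0, dtype=float)
        if config.theta0 is not None
        else target.initial_point()
    )
    cur = target.evaluate(theta, order=order)
    if not cur.ok:
        raise RuntimeError(f"initial point evaluation failed: {cur.error}")

    total = config.burn_in + config.n_samples
    m = len(cur.theta)
    thetas = np.empty((config.n_samples, m))
    loglik = np.empty(config.n_samples)
    logpost = np.empty(config.n_samples)
    accepted = np.empty(config.n_samples, dtype=bool)
    delta_h = np.empty(config.n_samples)
    fallbacks = np.empty(config.n_samples, dtype=int)

    consec_fail = 0
    t0 = time.perf_counter()
    t_start_sampling = t0
    for i in range(total):
        if i == config.burn_in:
            t_start_sampling = time.perf_counter()
        cur, rec = kernel(cur, target, config, rng)
        if i < 50:
            consec_fail = consec_fail + 1 if not np.isfinite(rec["delta_h"]) else 0
            if consec_fail >= 25:
                raise RuntimeError(
                    "backend failed for 25 consecutive proposals early in the run; "
                    "reduce eps or switch backend/starting point"
                )
        if i >= config.burn_in:
            k = i - config.burn_in
            thetas[k] = rec["theta"]
            loglik[k] = rec["loglik"]
            logpost[k] = rec["logpost"]
            accepted[k] = rec["accepted"]
            delta_h[k] = rec["delta_h"]
            fallbacks[k] = rec["fallbacks"]
    t_elapsed = time.perf_counter() - t_start_sampling if config.n_samples else 0.0

    return Chain(
        thetas=thetas,
        loglik=loglik,
        logpost=logpost,
        accepted=accepted,
        delta_h=delta_h,
        fallbacks=fallbacks,
        t_elapsed=t_elapsed,
        config=config,
        parameter_names=parameter_names,
    )


def run_chain(model, dataset: Dataset, prior: GaussianPrior, config: SamplerConfig) -> Chain:
    """Sample the steady-state posterior of ``model`` given ``dataset`` and ``prior``."""
    target = SteadyStatePosterior(model, dataset, prior, backend=config.backend)
    return sample_target(target, config, parameter_names=model.parameter_names)


def tune_epsilon(
    target,
    config: SamplerConfig,
    accept_range=(0.8, 0.95),
    pilot_samples: int = 100,
    max_rounds: int = 12,
) -> float:
    """Pilot-run step-size tuner targeting an acceptance-rate window.

    Runs short pilot chains, multiplying/dividing ``eps`` by 1.5 until the
    acceptance rate falls inside ``accept_range`` (defaults suit HMC; use e.g.
    ``(0.5, 0.7)`` for SMMALA).  Returns the tuned ``eps``; ``config`` is not
    modified.
    """
    from dataclasses import replace

    eps = config.eps
    lo, hi = accept_range
    for _ in range(max_rounds):
        pilot = replace(config, eps=eps, n_samples=pilot_samples, burn_in=pilot_samples // 5)
        chain = sample_target(target, pilot)
        if hasattr(target, "reset_anchor"):
            target.reset_anchor()
        rate = chain.acceptance_rate
        if rate < lo:
            eps /= 1.5
        elif rate > hi:
            eps *= 1.5
        else:
            break
    return eps
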