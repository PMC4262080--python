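"""Steady states and their parameter sensitivities.

Two routes to the fixed point ``f(xbar, theta, u) = 0``:

* :func:`solve_by_integration` — integrate the initial value problem from the
  known ``x0`` with a stiff-capable solver until the residual stays below
  tolerance (the baseline used to initialise every chain, and the workhorse of
  the baseline samplers);
* :func:`newton_refine` — a multivariate Newton-Raphson iteration seeded by the
  first-order prediction :func:`predict_steady_state_shift`, used to *track*
  the steady state along Hamiltonian trajectories where parameter moves are
  small.

Once a steady state is known, the implicit function theorem turns sensitivity
analysis into linear algebra: the first-order sensitivity ``S = dxbar/dtheta``
solves ``J_f S = -df/dtheta`` and the second-order tensor ``S2`` solves another
linear system with the same LU-factorised Jacobian, so no dynamic sensitivity
integration is ever required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .model import ODEModel, ModelEvaluationError

__all__ = [
    "SteadyStateError",
    "SteadyStateResult",
    "solve_by_integration",
    "predict_steady_state_shift",
    "newton_refine",
    "first_order_sensitivity",
    "second_order_sensitivity",
    "second_order_rhs",
    "solve_steady_state",
]


class SteadyStateError(RuntimeError):
    """No steady state could be produced (non-convergence or singular Jacobian)."""


@dataclass
class SteadyStateResult:
    """A fixed point with (optional) sensitivity information.

    ``lu_factors`` holds the LU decomposition of ``J_f(xbar)`` so that first-
    and second-order sensitivity solves can share one factorisation.
    """

    xbar: np.ndarray
    residual_norm: float
    method: str  # "integration" | "newton"
    S: np.ndarray | None = None
    S2: np.ndarray | None = None
    lu_factors: tuple | None = None
    n_iter: int = 0
    residual_history: list[float] | None = None


def _as_rhs(model: ODEModel, theta, u):
    def rhs(t, x):
        return model.f(x, theta, u)

    def jac(t, x):
        return model.f_x(x, theta, u)

    return rhs, jac


def solve_by_integration(
    model: ODEModel,
    theta,
    u,
    convergence_tol: float = 1e-8,
    t_max: float = 1e7,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    x0=None,
) -> np.ndarray:
    """Integrate the IVP from ``x0`` until the vector field has converged.

    Convergence means ``||f(x)||_inf <= convergence_tol`` sustained over two
    consecutive (doubling) reporting intervals.  Raises
    :class:`SteadyStateError` when ``t_max`` is exceeded, which callers treat
    as log-likelihood ``-inf`` (the proposal is rejected).
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise SteadyStateError("non-finite parameters")
    x = np.array(model.initial_condition if x0 is None else x0, dtype=float)
    rhs, jac = _as_rhs(model, theta, u)
    return _integrate_to_steady_state(rhs, jac, x, convergence_tol, t_max, rtol, atol)


def _integrate_to_steady_state(rhs, jac, x0, tol, t_max, rtol, atol):
    """Integrate until ``||f||_inf <= tol`` sustained over two reporting intervals.

    Uses the continuing LSODA interface (no solver restarts): the residual is
    checked at geometrically growing reporting times, and convergence requires
    two consecutive passing checks so a transient dip of a non-monotone
    residual does not terminate the run early.
    """
    from scipy.integrate import ode

    x0 = np.asarray(x0, dtype=float)
    if float(np.max(np.abs(rhs(0.0, x0)))) <= tol:
        return x0
    solver = ode(rhs, jac)
    solver.set_integrator("lsoda", rtol=rtol, atol=atol, nsteps=100000)
    solver.set_initial_value(x0, 0.0)
    t = 1.0
    ok_streak = 0
    while t <= t_max:
        x = solver.integrate(t)
        if not solver.successful():
            raise SteadyStateError(f"integrator failed at t={t:g}")
        if float(np.max(np.abs(rhs(t, x)))) <= tol:
            ok_streak += 1
            if ok_streak >= 2:
                return np.asarray(x, dtype=float)
        else:
            ok_streak = 0
        t *= 2.0
    raise SteadyStateError(f"no steady state within t_max={t_max:g}")


def predict_steady_state_shift(xbar, S, dtheta) -> np.ndarray:
    """First-order steady-state prediction ``x = xbar + S dtheta``.

    This is the estimate used to seed Newton-Raphson after each small
    parameter step along a Hamiltonian trajectory; its error is second order
    in ``||dtheta||``.
    """
    return np.asarray(xbar, dtype=float) + np.asarray(S, dtype=float) @ np.asarray(
        dtheta, dtype=float
    )


def newton_refine(
    model: ODEModel,
    theta,
    u,
    x_guess,
    tol: float | None = None,
    max_iter: int = 20,
) -> SteadyStateResult:
    """Newton-Raphson iteration ``x <- x - J_f(x)^-1 f(x)`` to the fixed point.

    ``tol=None`` uses the default ``||f||_inf <= 1e-9 * (1 + ||x||_inf)``.
    Raises :class:`SteadyStateError` on a singular Jacobian or when the
    residual grows for three consecutive iterations (divergence); callers fall
    back to :func:`solve_by_integration`.
    """
    x = np.array(x_guess, dtype=float)
    prev_res = np.inf
    grow = 0
    history: list[float] = []
    for it in range(1, max_iter + 1):
        try:
            f, J, _ = model.first_bundle(x, theta, u)
        except (ModelEvaluationError, FloatingPointError) as exc:
            raise SteadyStateError(f"model evaluation failed: {exc}") from None
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(J))):
            raise SteadyStateError("non-finite evaluation during Newton iteration")
        res = float(np.max(np.abs(f)))
        history.append(res)
        limit = tol if tol is not None else 1e-9 * (1.0 + float(np.max(np.abs(x))))
        lu = sla.lu_factor(J)
        if np.min(np.abs(np.diag(lu[0]))) < 1e-14 * max(1.0, np.max(np.abs(J))):
            raise SteadyStateError(f"singular Jacobian at Newton iterate {it}")
        if res <= limit:
            return SteadyStateResult(
                xbar=x,
                residual_norm=res,
                method="newton",
                lu_factors=lu,
                n_iter=it - 1,
                residual_history=history,
            )
        if res > prev_res:
            grow += 1
            if grow >= 3:
                raise SteadyStateError("Newton iteration diverging")
        else:
            grow = 0
        prev_res = res
        x = x - sla.lu_solve(lu, f)
    raise SteadyStateError(f"Newton did not converge in {max_iter} iterations")


def first_order_sensitivity(model: ODEModel, theta, u, xbar, lu_factors=None) -> np.ndarray:
    """Solve ``J_f S = -df/dtheta`` column-wise with one LU factorisation.

    A singular Jacobian raises :class:`SteadyStateError` mentioning the likely
    cause (an unreduced conservation relation).
    """
    f, J, fth = model.first_bundle(xbar, theta, u)
    if lu_factors is None:
        lu_factors = sla.lu_factor(J)
    if np.min(np.abs(np.diag(lu_factors[0]))) < 1e-14 * max(1.0, np.max(np.abs(J))):
        raise SteadyStateError(
            "singular steady-state Jacobian: the model is rank deficient "
            "(did you forget to reduce a conservation relation?)"
        )
    return sla.lu_solve(lu_factors, -fth)


def second_order_rhs(f_xx, f_xtheta, f_thetatheta, S) -> np.ndarray:
    """Right-hand side of the linear system for the second-order sensitivity.

    Differentiating ``J_f S_s + f_theta_s = 0`` once more in ``theta_r`` gives
    ``J_f S2[:, s, r] = -(f_thetatheta[:, s, r] + f_xtheta[:, :, s] S_r
    + (f_xtheta[:, :, r] + f_xx : S_r) S_s)``; this function assembles that
    (symmetric in ``(r, s)``) right-hand side.
    """
    t1 = np.einsum("ikr,ks->isr", f_xtheta, S)
    t2 = np.einsum("ikl,lr,ks->isr", f_xx, S, S)
    t3 = np.einsum("ils,lr->isr", f_xtheta, S)
    return -(t1 + t2 + f_thetatheta + t3)


def second_order_sensitivity(model: ODEModel, theta, u, xbar, S, lu_factors) -> np.ndarray:
    """Solve for ``S2[i, r, s] = d2 xbar_i / dtheta_r dtheta_s``.

    Reuses the LU factors from the first-order solve; the result is symmetric
    in its two parameter indices.
    """
    f_xx, f_xth, f_thth = model.second_bundle(xbar, theta, u)
    rhs = second_order_rhs(f_xx, f_xth, f_thth, S)
    n, m = S.shape
    flat = rhs.reshape(n, m * m)
    S2 = sla.lu_solve(lu_factors, flat).reshape(n, m, m)
    # enforce exact symmetry against round-off
    return 0.5 * (S2 + np.swapaxes(S2, 1, 2))


def solve_steady_state(
    model: ODEModel,
    theta,
    u,
    order: int = 2,
    convergence_tol: float = 1e-8,
    newton_polish: bool = True,
    **integrate_kwargs,
) -> SteadyStateResult:
    """Convenience: integrate to the steady state and attach sensitivities."""
    x = solve_by_integration(model, theta, u, convergence_tol=convergence_tol, **integrate_kwargs)
    if newton_polish:
        result = newton_refine(model, theta, u, x)
    else:
        f, J, _ = model.first_bundle(x, theta, u)
        result = SteadyStateResult(
            xbar=x,
            residual_norm=float(np.max(np.abs(f))),
            method="integration",
            lu_factors=sla.lu_factor(J),
        )
    if order >= 1:
        result.S = first_order_sensitivity(model, theta, u, result.xbar, result.lu_factors)
    if order >= 2:
        result.S2 = second_order_sensitivity(
            model, theta, u, result.xbar, result.S, result.lu_factors
        )
    return result
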