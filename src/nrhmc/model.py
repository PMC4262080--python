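"""Symbolic steady-state ODE models of biochemical reaction networks.

A model is a smooth vector field ``dx/dt = f(x, rho, u)`` describing molecular
concentrations ``x`` under constant experimental inputs ``u`` (knockdown levels,
ligand doses, ...), with strictly positive kinetic parameters ``rho``, a known
unparameterised initial condition ``x0`` and a linear observation map
``h(x) = C x + c0``.

Because rate constants are positive, inference happens in logarithmic parameter
space ``theta = log(rho)``.  The log transform is baked into the symbolic vector
field once at build time, so every derivative produced here — the state Jacobian
``J_f = df/dx``, the parameter Jacobian ``df/dtheta`` and the three second-order
slabs ``d2f/dxdx``, ``d2f/dxdtheta``, ``d2f/dthetadtheta`` — already carries the
chain-rule factor ``rho = exp(theta)``.  Downstream modules never see natural
parameters.

Models with linear conservation relations (e.g. total receptor pools) have a
singular Jacobian everywhere; :func:`reduce_by_conservation` eliminates one
species per conserved sum to restore invertibility.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from math import prod
from typing import Sequence

import numpy as np
import sympy as sp
from sympy.parsing.sympy_parser import (
    parse_expr,
    standard_transformations,
    convert_xor,
)

__all__ = [
    "ODEModel",
    "ConservationReduction",
    "ModelSpecError",
    "ModelEvaluationError",
    "build_model",
    "load_model",
    "parse_model_spec",
    "reduce_by_conservation",
    "evaluate_model",
    "ModelDerivatives",
]

_TRANSFORMS = standard_transformations + (convert_xor,)
# minimal namespace for parse_expr: the allowed functions plus the numeric
# constructors the parser itself emits for literals
_ALLOWED_FUNCS = {
    "exp": sp.exp,
    "log": sp.log,
    "sqrt": sp.sqrt,
    "Integer": sp.Integer,
    "Float": sp.Float,
    "Rational": sp.Rational,
    "Symbol": sp.Symbol,
}
_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")

_SECTION_NAMES = {
    "states",
    "parameters",
    "inputs",
    "ode",
    "output_matrix",
    "initial_condition",
    "conserved_sums",
}


class ModelSpecError(ValueError):
    """Raised when a model specification cannot be parsed or is inconsistent."""


class ModelEvaluationError(RuntimeError):
    """Raised when evaluating model derivatives yields non-finite values.

    Carries the offending evaluation point as attributes ``x``, ``theta``, ``u``.
    """

    def __init__(self, message, x=None, theta=None, u=None):
        super().__init__(message)
        self.x = x
        self.theta = theta
        self.u = u


def parse_model_spec(text: str) -> dict:
    """Parse the plain structured-text model format into raw sections.

    The format has bracketed sections ``[states]``, ``[parameters]``,
    ``[inputs]`` (optional), ``[ode]`` (one expression per state),
    ``[output_matrix]`` (dense rows), ``[initial_condition]`` and optionally
    ``[conserved_sums]`` (one coefficient row per conserved linear combination).
    ``#`` starts a comment.  Expressions may use ``+ - * / ^ exp log sqrt``.
    """
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            name = line[1:-1].strip().lower()
            if name not in _SECTION_NAMES:
                raise ModelSpecError(f"unknown section [{name}]")
            if name in sections:
                raise ModelSpecError(f"duplicate section [{name}]")
            current = sections[name] = []
            continue
        if current is None:
            raise ModelSpecError(f"content before first section: {line!r}")
        current.append(line)

    for required in ("states", "parameters", "ode", "output_matrix", "initial_condition"):
        if required not in sections or not sections[required]:
            raise ModelSpecError(f"missing required section [{required}]")

    def idents(lines, what):
        names = []
        for ln in lines:
            names.extend(ln.split())
        for n in names:
            if not _IDENT_RE.match(n):
                raise ModelSpecError(f"invalid {what} identifier: {n!r}")
        if len(set(names)) != len(names):
            raise ModelSpecError(f"duplicate {what} identifiers")
        return names

    spec = {
        "states": idents(sections["states"], "state"),
        "parameters": idents(sections["parameters"], "parameter"),
        "inputs": idents(sections.get("inputs", []), "input"),
        "ode": sections["ode"],
        "output_matrix": _parse_matrix(sections["output_matrix"]),
        "initial_condition": _parse_vector(sections["initial_condition"]),
        "conserved_sums": (
            _parse_matrix(sections["conserved_sums"]) if "conserved_sums" in sections else None
        ),
    }
    return spec


def _parse_matrix(lines: list[str]) -> np.ndarray:
    try:
        rows = [[float(v) for v in ln.split()] for ln in lines]
    except ValueError as exc:
        raise ModelSpecError(f"non-numeric matrix entry: {exc}") from None
    if len({len(r) for r in rows}) != 1:
        raise ModelSpecError("ragged matrix rows")
    return np.array(rows, dtype=float)


def _parse_vector(lines: list[str]) -> np.ndarray:
    vals = []
    for ln in lines:
        vals.extend(float(v) for v in ln.split())
    return np.array(vals, dtype=float)


class _Bundle:
    """A lambdified flat list of expressions, reshaped into named arrays.

    Supports single-point evaluation (``x`` of shape ``(n,)``) and batched
    evaluation over experiments (``x`` of shape ``(B, n)``, ``u`` of shape
    ``(B, n_u)``, shared ``theta``), in which case every output gains a
    leading batch axis.
    """

    def __init__(self, args, exprs_by_shape):
        self.shapes = [shape for shape, _ in exprs_by_shape]
        flat = []
        for _, exprs in exprs_by_shape:
            flat.extend(exprs)
        self._sizes = [prod(s) for s in self.shapes]
        self._fn = sp.lambdify(args, flat, modules="numpy", cse=True)
        self._n_x = 0  # set by owner

    def __call__(self, x, theta, u):
        x = np.asarray(x, dtype=float)
        theta = np.asarray(theta, dtype=float)
        u = np.asarray(u, dtype=float)
        batched = x.ndim == 2
        if batched:
            if u.ndim != 2:
                u = np.broadcast_to(u, (x.shape[0], u.shape[-1] if u.size else 0))
            args = [x[:, i] for i in range(x.shape[1])]
            args += list(theta)
            args += [u[:, i] for i in range(u.shape[1])]
            out = self._fn(*args)
            b = x.shape[0]
            cols = np.empty((len(out), b), dtype=float)
            for k, v in enumerate(out):
                cols[k] = v  # broadcasts scalars
            arrays = []
            start = 0
            for shape, size in zip(self.shapes, self._sizes):
                chunk = cols[start : start + size]
                arrays.append(np.moveaxis(chunk.reshape(shape + (b,)), -1, 0))
                start += size
            return tuple(arrays)
        out = self._fn(*x, *theta, *u)
        flat = np.asarray(out, dtype=float)
        arrays = []
        start = 0
        for shape, size in zip(self.shapes, self._sizes):
            arrays.append(flat[start : start + size].reshape(shape))
            start += size
        return tuple(arrays)


@dataclass
class ModelDerivatives:
    """Numeric derivative slabs of the vector field at one point."""

    f: np.ndarray
    f_x: np.ndarray
    f_theta: np.ndarray
    f_xx: np.ndarray | None = None
    f_xtheta: np.ndarray | None = None
    f_thetatheta: np.ndarray | None = None


class ODEModel:
    """A steady-state ODE model with its full symbolic derivative bundle.

    Parameters are handled in log space: callables take ``theta = log(rho)``.
    Instances are immutable after construction and evaluation is side-effect
    free.
    """

    def __init__(
        self,
        state_names: Sequence[str],
        parameter_names: Sequence[str],
        input_names: Sequence[str],
        f_natural: Sequence[sp.Expr],
        output_matrix: np.ndarray,
        initial_condition: np.ndarray,
        output_offset: np.ndarray | None = None,
        input_set: np.ndarray | None = None,
    ):
        self.state_names = tuple(state_names)
        self.parameter_names = tuple(parameter_names)
        self.input_names = tuple(input_names)
        n, m = len(self.state_names), len(self.parameter_names)
        if len(f_natural) != n:
            raise ModelSpecError(
                f"{len(f_natural)} ODE expressions for {n} states"
            )
        self.output_matrix = np.atleast_2d(np.asarray(output_matrix, dtype=float))
        if self.output_matrix.shape[1] != n:
            raise ModelSpecError("output matrix must have one column per state")
        self.output_offset = (
            np.zeros(self.output_matrix.shape[0])
            if output_offset is None
            else np.asarray(output_offset, dtype=float)
        )
        self.initial_condition = np.asarray(initial_condition, dtype=float)
        if self.initial_condition.shape != (n,):
            raise ModelSpecError("initial condition length must equal state count")
        self.input_set = None if input_set is None else np.atleast_2d(input_set)

        self._x = [sp.Symbol(s, real=True) for s in self.state_names]
        self._rho = [sp.Symbol(p, real=True, positive=True) for p in self.parameter_names]
        self._u = [sp.Symbol(s, real=True) for s in self.input_names]
        self._theta = [sp.Symbol(f"_theta_{p}", real=True) for p in self.parameter_names]

        self.f_natural = tuple(sp.sympify(e) for e in f_natural)
        log_sub = dict(zip(self._rho, [sp.exp(t) for t in self._theta]))
        self.f_sym = tuple(e.xreplace(log_sub) for e in self.f_natural)

        fx = [[sp.diff(fi, xj) for xj in self._x] for fi in self.f_sym]
        fth = [[sp.diff(fi, tj) for tj in self._theta] for fi in self.f_sym]
        self.state_jacobian = tuple(tuple(r) for r in fx)
        self.parameter_jacobian = tuple(tuple(r) for r in fth)

        args = (*self._x, *self._theta, *self._u)
        flat1 = [
            ((n,), list(self.f_sym)),
            ((n, n), [e for row in fx for e in row]),
            ((n, m), [e for row in fth for e in row]),
        ]
        self._bundle1 = _Bundle(args, flat1)
        # lean single-purpose callables for ODE integration right-hand sides
        self._bundle_f = _Bundle(args, [((n,), list(self.f_sym))])
        self._bundle_jac = _Bundle(args, [((n, n), [e for row in fx for e in row])])
        self._fx_sym = fx
        self._fth_sym = fth
        self._bundle2 = None  # built lazily; second-order slabs are only
        # needed by the Riemannian samplers / metric derivatives

    # -- sizes ---------------------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    # -- symbolic second-order bundle (lazy) ---------------------------------

    def _second_bundle(self) -> _Bundle:
        if self._bundle2 is None:
            n, m = self.n_states, self.n_parameters
            x, th = self._x, self._theta
            fx, fth = self._fx_sym, self._fth_sym
            # exploit symmetry: differentiate the upper triangle and mirror
            fxx = [[[None] * n for _ in range(n)] for _ in range(n)]
            for i in range(n):
                for j in range(n):
                    for k in range(j, n):
                        d = sp.diff(fx[i][j], x[k])
                        fxx[i][j][k] = d
                        fxx[i][k][j] = d
            fxth = [
                [[sp.diff(fx[i][j], th[r]) for r in range(m)] for j in range(n)]
                for i in range(n)
            ]
            fthth = [[[None] * m for _ in range(m)] for _ in range(n)]
            for i in range(n):
                for r in range(m):
                    for s in range(r, m):
                        d = sp.diff(fth[i][r], th[s])
                        fthth[i][r][s] = d
                        fthth[i][s][r] = d
            args = (*self._x, *self._theta, *self._u)
            flat2 = [
                ((n, n, n), [e for a in fxx for b in a for e in b]),
                ((n, n, m), [e for a in fxth for b in a for e in b]),
                ((n, m, m), [e for a in fthth for b in a for e in b]),
            ]
            self._bundle2 = _Bundle(args, flat2)
        return self._bundle2

    # -- numeric evaluation --------------------------------------------------

    def f(self, x, theta, u) -> np.ndarray:
        return self._bundle_f(x, theta, self._coerce_u(u, x))[0]

    def f_x(self, x, theta, u) -> np.ndarray:
        return self._bundle_jac(x, theta, self._coerce_u(u, x))[0]

    def f_theta(self, x, theta, u) -> np.ndarray:
        return self.first_bundle(x, theta, u)[2]

    def first_bundle(self, x, theta, u):
        """Return ``(f, J_f, df/dtheta)`` at one point or a batch of points."""
        return self._bundle1(x, theta, self._coerce_u(u, x))

    def second_bundle(self, x, theta, u):
        """Return ``(d2f/dxdx, d2f/dxdtheta, d2f/dthetadtheta)``."""
        return self._second_bundle()(x, theta, self._coerce_u(u, x))

    def output(self, x) -> np.ndarray:
        """Observable model output ``h(x) = C x + c0``."""
        x = np.asarray(x, dtype=float)
        return x @ self.output_matrix.T + self.output_offset

    def _coerce_u(self, u, x):
        u = np.atleast_1d(np.asarray(u, dtype=float))
        if np.asarray(x).ndim == 2 and u.ndim == 1:
            u = np.broadcast_to(u, (np.asarray(x).shape[0], u.shape[0]))
        if u.shape[-1] != self.n_inputs:
            raise ModelEvaluationError(
                f"expected {self.n_inputs} inputs, got {u.shape[-1]}", u=u
            )
        return u

    def __repr__(self):
        return (
            f"ODEModel(n_states={self.n_states}, n_parameters={self.n_parameters}, "
            f"n_inputs={self.n_inputs})"
        )


def build_model(spec: str | dict) -> ODEModel:
    """Build an :class:`ODEModel` from specification text (or parsed sections).

    Parsing rejects malformed expressions and undeclared identifiers.  Any
    conserved sums declared in the spec are *not* applied automatically; pass
    them to :func:`reduce_by_conservation` (the parsed coefficients are kept on
    the returned model as ``declared_conserved_sums``).
    """
    parsed = parse_model_spec(spec) if isinstance(spec, str) else dict(spec)
    states, params, inputs = parsed["states"], parsed["parameters"], parsed["inputs"]
    all_names = set(states) | set(params) | set(inputs)
    if len(all_names) != len(states) + len(params) + len(inputs):
        raise ModelSpecError("state/parameter/input names must be distinct")
    local = {name: sp.Symbol(name, real=True) for name in states + inputs}
    local.update({name: sp.Symbol(name, real=True, positive=True) for name in params})

    exprs = []
    for text in parsed["ode"]:
        try:
            e = parse_expr(
                text,
                local_dict=local,
                global_dict=dict(_ALLOWED_FUNCS),
                transformations=_TRANSFORMS,
                evaluate=True,
            )
        except Exception as exc:  # sympy raises many flavours here
            raise ModelSpecError(f"cannot parse expression {text!r}: {exc}") from None
        unknown = {str(s) for s in e.free_symbols} - all_names
        if unknown:
            raise ModelSpecError(
                f"undeclared identifier(s) {sorted(unknown)} in expression {text!r}"
            )
        exprs.append(e)
    if len(exprs) != len(states):
        raise ModelSpecError(f"{len(exprs)} ODE expressions for {len(states)} states")

    model = ODEModel(
        state_names=states,
        parameter_names=params,
        input_names=inputs,
        f_natural=exprs,
        output_matrix=parsed["output_matrix"],
        initial_condition=parsed["initial_condition"],
    )
    model.declared_conserved_sums = parsed.get("conserved_sums")
    return model


def load_model(path) -> ODEModel:
    """Read a model specification file and build the model."""
    with open(path) as fh:
        return build_model(fh.read())


def evaluate_model(model: ODEModel, x, theta, u, second_order: bool = True) -> ModelDerivatives:
    """Evaluate the vector field and its derivative bundle at one point.

    Returns finite numeric arrays; a non-finite result raises
    :class:`ModelEvaluationError` carrying the offending point.
    """
    f, fx, fth = model.first_bundle(x, theta, u)
    out = ModelDerivatives(f=f, f_x=fx, f_theta=fth)
    arrays = [f, fx, fth]
    if second_order:
        fxx, fxth, fthth = model.second_bundle(x, theta, u)
        out.f_xx, out.f_xtheta, out.f_thetatheta = fxx, fxth, fthth
        arrays += [fxx, fxth, fthth]
    if not all(np.all(np.isfinite(a)) for a in arrays):
        raise ModelEvaluationError(
            "non-finite model evaluation", x=np.asarray(x), theta=np.asarray(theta), u=np.asarray(u)
        )
    return out


@dataclass
class ConservationReduction:
    """Bookkeeping for a conservation-relation state reduction.

    ``coefficients`` are the conserved-sum rows (over the *full* state),
    ``totals`` their constant values fixed by the initial condition, and
    ``substitutions`` express each eliminated species as an affine function of
    the retained states.  :meth:`reconstruct` rebuilds the full state vector.
    """

    coefficients: np.ndarray
    totals: np.ndarray
    eliminated_indices: tuple[int, ...]
    retained_indices: tuple[int, ...]
    full_state_names: tuple[str, ...]
    substitutions: dict[str, str]
    _affine: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)

    def reconstruct(self, x_reduced: np.ndarray) -> np.ndarray:
        """Map reduced states back to the full species vector."""
        x_reduced = np.asarray(x_reduced, dtype=float)
        A, b = self._affine
        x_elim = x_reduced @ A.T + b
        full = np.empty(x_reduced.shape[:-1] + (len(self.full_state_names),))
        full[..., list(self.retained_indices)] = x_reduced
        full[..., list(self.eliminated_indices)] = x_elim
        return full


def reduce_by_conservation(model: ODEModel, conserved_sums) -> tuple[ODEModel, ConservationReduction]:
    """Eliminate one species per conserved linear combination.

    Each row of ``conserved_sums`` must be a left null vector of the vector
    field (the time derivative of the sum is symbolically zero); otherwise the
    row is rejected.  The eliminated species are replaced everywhere in ``f``
    (and in the output map, which may acquire a constant offset) by
    total-minus-rest substitutions, with totals fixed by the known initial
    condition.  An empty sum list returns the model unchanged.
    """
    sums = np.atleast_2d(np.asarray(conserved_sums, dtype=float))
    if sums.size == 0:
        empty = ConservationReduction(
            coefficients=np.zeros((0, model.n_states)),
            totals=np.zeros(0),
            eliminated_indices=(),
            retained_indices=tuple(range(model.n_states)),
            full_state_names=model.state_names,
            substitutions={},
            _affine=(np.zeros((0, model.n_states)), np.zeros(0)),
        )
        return model, empty
    if sums.shape[1] != model.n_states:
        raise ModelSpecError("conserved sum length must equal state count")

    x = model._x
    # verify each sum is conserved: d/dt (c . x) == 0 identically
    for row in sums:
        ddt = sp.expand(sum(c * fi for c, fi in zip(row, model.f_natural)))
        if sp.simplify(ddt) != 0:
            raise ModelSpecError(
                f"proposed sum {row.tolist()} is not conserved: d/dt = {ddt}"
            )

    totals = sums @ model.initial_condition
    observed_cols = np.any(model.output_matrix != 0.0, axis=0)

    eliminated: list[int] = []
    for row in sums:
        nz = [i for i in np.flatnonzero(row) if i not in eliminated]
        if not nz:
            raise ModelSpecError("conserved sums are linearly dependent")
        # prefer eliminating an unobserved species so C keeps its meaning
        unobs = [i for i in nz if not observed_cols[i]]
        eliminated.append((unobs or nz)[0])
    retained = [i for i in range(model.n_states) if i not in eliminated]

    elim_syms = [x[i] for i in eliminated]
    eqs = [
        sp.Eq(sum(row[i] * x[i] for i in range(model.n_states)), tot)
        for row, tot in zip(sums, totals)
    ]
    sol = sp.solve(eqs, elim_syms, dict=True)
    if not sol:
        raise ModelSpecError("could not solve conservation relations for eliminated species")
    sub = {s: sp.expand(e) for s, e in sol[0].items()}

    f_red = [sp.expand(model.f_natural[i].xreplace(sub)) for i in retained]

    # fold the substitution through the linear output map; it stays affine
    ret_syms = [x[i] for i in retained]
    C_new = np.zeros((model.output_matrix.shape[0], len(retained)))
    offset = model.output_offset.copy()
    for r in range(model.output_matrix.shape[0]):
        expr = sum(
            model.output_matrix[r, j] * (sub.get(x[j], x[j])) for j in range(model.n_states)
        )
        expr = sp.expand(expr)
        for k, s in enumerate(ret_syms):
            C_new[r, k] = float(expr.coeff(s))
        offset[r] += float(expr.subs({s: 0 for s in ret_syms}))

    reduced = ODEModel(
        state_names=[model.state_names[i] for i in retained],
        parameter_names=model.parameter_names,
        input_names=model.input_names,
        f_natural=f_red,
        output_matrix=C_new,
        initial_condition=model.initial_condition[retained],
        output_offset=offset,
        input_set=model.input_set,
    )

    A = np.zeros((len(eliminated), len(retained)))
    b = np.zeros(len(eliminated))
    for row_idx, s in enumerate(elim_syms):
        expr = sub[s]
        for k, rs in enumerate(ret_syms):
            A[row_idx, k] = float(expr.coeff(rs))
        b[row_idx] = float(expr.subs({rs: 0 for rs in ret_syms}))

    reduction = ConservationReduction(
        coefficients=sums,
        totals=totals,
        eliminated_indices=tuple(eliminated),
        retained_indices=tuple(retained),
        full_state_names=model.state_names,
        substitutions={str(s): str(e) for s, e in sub.items()},
        _affine=(A, b),
    )
    return reduced, reduction
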