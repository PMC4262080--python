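"""Ready-made example models, perturbation designs and a synthetic-data generator.

Four fixtures of increasing size:

* ``linear_toy`` — one state, one parameter, closed-form everything; the
  oracle model for unit tests (steady state ``u exp(-theta)``).
* ``mapk_erk`` — phosphorylation of Erk in the MAPK cascade: a two-state,
  two-parameter distributive phosphorylation cycle whose total Erk amount is
  the experimental input ``u = Erk_T`` (knockdown experiments), with the
  phosphorylation rate multiplied by the negative-feedback factor
  ``u / (1 + u)``.  Output: doubly phosphorylated Erk.
* ``insulin_mma`` — a minimal insulin-receptor/IRS phosphorylation model:
  5 molecular species (IR, IRP, internalised IR*, IRS, IRSP) with two
  built-in conservation relations, reduced to 3 independent states with
  6 parameters.  The scalar input is the insulin dose; the output is IRSP
  scaled by a fixed (not sampled) output coefficient C_{1,3}.
  ``insulin_mma_full`` ships the unreduced 5-species variant to exercise
  conservation-relation reduction.
* ``insulin_mifa`` — a larger insulin model (6 reduced states, 14 parameters)
  with receptor internalisation feeding IRS phosphorylation and a
  negative-feedback loop via PKB and a downstream effector.

The insulin fixtures are synthetic stand-ins: structurally faithful to the
published model family (species pools, conservation relations, dose-response
read-out) but with rate equations and reference parameters chosen here.  The
dataset generator emulates steady-state perturbation measurements: it solves
the model at the design's true parameters and adds Gaussian noise of known
scale, keeping the noise-free outputs alongside for test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .model import ODEModel, build_model
from .posterior import Dataset, Experiment, GaussianPrior
from .steady_state import SteadyStateError, newton_refine, solve_by_integration

__all__ = [
    "SyntheticDesign",
    "linear_toy",
    "mapk_erk",
    "insulin_mma",
    "insulin_mma_full",
    "insulin_mifa",
    "fixture",
    "FIXTURE_NAMES",
    "theta_true",
    "default_prior",
    "mapk_design",
    "insulin_design",
    "generate_dataset",
]


LINEAR_TOY_SPEC = """
# one-state linear relaxation: dx/dt = u - k x, steady state u/k
[states]
x
[parameters]
k
[inputs]
drive
[ode]
drive - k*x
[output_matrix]
1
[initial_condition]
0
"""

MAPK_ERK_SPEC = """
# Distributive two-site Erk phosphorylation with total Erk u = Erk_T as input.
# The phosphorylation rate carries the negative-feedback factor u/(1+u);
# unphosphorylated Erk is expressed through the total: Erk = u - pErk - ppErk.
[states]
pErk
ppErk
[parameters]
k_phos
k_dephos
[inputs]
Erk_T
[ode]
k_phos*Erk_T/(1 + Erk_T)*(Erk_T - pErk - ppErk) - k_phos*Erk_T/(1 + Erk_T)*pErk - k_dephos*pErk + k_dephos*ppErk
k_phos*Erk_T/(1 + Erk_T)*pErk - k_dephos*ppErk
[output_matrix]
0 1
[initial_condition]
0 0
"""

INSULIN_MMA_SPEC = """
# Minimal insulin receptor / IRS phosphorylation model, conservation-reduced:
# receptor pool IR + IRP + IRstar = 1, substrate pool IRS + IRSP = 1.
# States: IRP (phosphorylated receptor), IRstar (internalised), IRSP.
# Output coefficient C_{1,3} = 2.5 is a fixed measurement scale, not sampled.
[states]
IRP
IRstar
IRSP
[parameters]
k_act
k_intern
k_recyc
k_phosIRS
k_dephosIRS
k_dephosIR
[inputs]
insulin
[ode]
k_act*insulin*(1 - IRP - IRstar) - (k_intern + k_dephosIR)*IRP
k_intern*IRP - k_recyc*IRstar
k_phosIRS*IRP*(1 - IRSP) - k_dephosIRS*IRSP
[output_matrix]
0 0 2.5
[initial_condition]
0 0 0
"""

INSULIN_MMA_FULL_SPEC = """
# Unreduced 5-species variant of the minimal insulin model; the two conserved
# sums make the Jacobian singular everywhere until the model is reduced.
[states]
IR
IRP
IRstar
IRS
IRSP
[parameters]
k_act
k_intern
k_recyc
k_phosIRS
k_dephosIRS
k_dephosIR
[inputs]
insulin
[ode]
-k_act*insulin*IR + k_recyc*IRstar + k_dephosIR*IRP
k_act*insulin*IR - (k_intern + k_dephosIR)*IRP
k_intern*IRP - k_recyc*IRstar
-k_phosIRS*IRP*IRS + k_dephosIRS*IRSP
k_phosIRS*IRP*IRS - k_dephosIRS*IRSP
[output_matrix]
0 0 0 0 2.5
[initial_condition]
1 0 0 1 0
[conserved_sums]
1 1 1 0 0
0 0 0 1 1
"""

INSULIN_MIFA_SPEC = """
# Larger insulin model (conservation-reduced): receptor binding, activation,
# internalisation and recycling; IRS phosphorylation driven by active and
# internalised receptor; PKB cascade with negative feedback from the effector
# XP onto IRSP dephosphorylation.  Pools (each total 1): receptor
# IR + IRins + IRP + IRi, substrate IRS + IRSP, kinase PKB + PKBP,
# effector X + XP.
[states]
IRins
IRP
IRi
IRSP
PKBP
XP
[parameters]
k_bind
k_unbind
k_phosIR
k_intern
k_recyc
k_dephosIR
k_phosIRS
k_phosIRSi
k_dephosIRS
k_phosPKB
k_dephosPKB
k_phosX
k_dephosX
k_fb
[inputs]
insulin
[ode]
k_bind*insulin*(1 - IRins - IRP - IRi) - (k_unbind + k_phosIR)*IRins
k_phosIR*IRins - (k_intern + k_dephosIR)*IRP
k_intern*IRP - k_recyc*IRi
(k_phosIRS*IRP + k_phosIRSi*IRi)*(1 - IRSP) - k_dephosIRS*IRSP - k_fb*XP*IRSP
k_phosPKB*IRSP*(1 - PKBP) - k_dephosPKB*PKBP
k_phosX*PKBP*(1 - XP) - k_dephosX*XP
[output_matrix]
0 0 0 3.0 0 0
[initial_condition]
0 0 0 0 0 0
"""

_SPECS = {
    "linear_toy": LINEAR_TOY_SPEC,
    "mapk_erk": MAPK_ERK_SPEC,
    "insulin_mma": INSULIN_MMA_SPEC,
    "insulin_mma_full": INSULIN_MMA_FULL_SPEC,
    "insulin_mifa": INSULIN_MIFA_SPEC,
}

FIXTURE_NAMES = tuple(_SPECS)

_THETA_TRUE_NATURAL = {
    "linear_toy": np.array([1.0]),
    "mapk_erk": np.array([4.0, 1.0]),
    "insulin_mma": np.array([1.0, 0.5, 0.2, 2.0, 1.0, 0.3]),
    "insulin_mifa": np.array(
        [1.0, 0.2, 1.5, 0.6, 0.4, 0.3, 2.0, 0.3, 1.0, 1.5, 0.8, 1.0, 0.5, 0.8]
    ),
}
_THETA_TRUE_NATURAL["insulin_mma_full"] = _THETA_TRUE_NATURAL["insulin_mma"]


@lru_cache(maxsize=None)
def _build(name: str) -> ODEModel:
    return build_model(_SPECS[name])


def linear_toy() -> ODEModel:
    """The closed-form one-state oracle model."""
    return _build("linear_toy")


def mapk_erk() -> ODEModel:
    """Erk phosphorylation model: 2 states, 2 parameters, input Erk_T."""
    return _build("mapk_erk")


def insulin_mma() -> ODEModel:
    """Reduced minimal insulin model: 3 states, 6 parameters."""
    return _build("insulin_mma")


def insulin_mma_full() -> ODEModel:
    """Unreduced 5-species minimal insulin model (singular Jacobian)."""
    return _build("insulin_mma_full")


def insulin_mifa() -> ODEModel:
    """Larger insulin model: 6 reduced states, 14 parameters."""
    return _build("insulin_mifa")


def fixture(name: str) -> ODEModel:
    """Look a fixture model up by name."""
    if name not in _SPECS:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return _build(name)


def theta_true(name: str) -> np.ndarray:
    """Reference log-parameters at which synthetic data is generated."""
    return np.log(_THETA_TRUE_NATURAL[name])


def default_prior(model: ODEModel, variance: float = 4.0) -> GaussianPrior:
    """The vague log-space prior used with the fixtures (diagonal, variance 4)."""
    return GaussianPrior.vague(model.n_parameters, variance=variance)


@dataclass
class SyntheticDesign:
    """A reproducible synthetic steady-state experiment design."""

    theta_true: np.ndarray
    inputs: np.ndarray  # (n_E, n_inputs)
    sigma: float | np.ndarray
    observables: np.ndarray | None = None  # default: every output row once
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        self.theta_true = np.atleast_1d(np.asarray(self.theta_true, dtype=float))
        self.inputs = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        # sigma == 0 generates a noise-free dataset (oracle use only)
        if np.any(np.atleast_1d(self.sigma) < 0):
            raise ValueError("sigma must be non-negative")


def mapk_design(seed: int = 0) -> SyntheticDesign:
    """Ten graded Erk_T knockdown levels including the u = 1 control, sigma 0.2.

    The exact knockdown levels of the original experiments are not published
    alongside the model; a plausible evenly graded set in (0, 1] is used.
    """
    u = np.linspace(0.1, 1.0, 10)[:, None]
    return SyntheticDesign(
        theta_true=theta_true("mapk_erk"), inputs=u, sigma=0.2, seed=seed
    )


def insulin_design(model: str = "mma", seed: int = 0) -> SyntheticDesign:
    """Dose-response design: basal (dose 0) plus log-spaced insulin doses."""
    doses = np.concatenate([[0.0], np.logspace(-2, 2, 9)])[:, None]
    if model == "mma":
        return SyntheticDesign(
            theta_true=theta_true("insulin_mma"), inputs=doses, sigma=0.1, seed=seed
        )
    if model == "mifa":
        return SyntheticDesign(
            theta_true=theta_true("insulin_mifa"), inputs=doses, sigma=0.15, seed=seed
        )
    raise ValueError("model must be 'mma' or 'mifa'")


def generate_dataset(model: ODEModel, design: SyntheticDesign, rng=None) -> Dataset:
    """Emulate steady-state measurements: solve, observe, add Gaussian noise.

    ``y_ij = h_i(xbar(theta_true, u_j)) + sigma_ij * N(0,1)``.  The noise-free
    outputs are stored on each experiment as ``y_true``.  An unreachable
    steady state raises :class:`SteadyStateError` naming the offending input.
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    n_out = model.output_matrix.shape[0]
    obs = (
        np.arange(n_out) if design.observables is None else np.asarray(design.observables)
    )
    experiments = []
    for j, u in enumerate(design.inputs):
        try:
            x = solve_by_integration(model, design.theta_true, u)
            x = newton_refine(model, design.theta_true, u, x).xbar
        except SteadyStateError as exc:
            raise SteadyStateError(
                f"steady state unreachable for experiment {j + 1} (u={u}): {exc}"
            ) from None
        y_true = model.output(x)[obs]
        sig = np.broadcast_to(np.atleast_1d(design.sigma), y_true.shape).astype(float)
        for _ in range(design.replicates):
            noise = rng.standard_normal(y_true.shape)
            experiments.append(
                Experiment(
                    u=u,
                    observables=obs,
                    y=y_true + sig * noise,
                    sigma=sig.copy(),
                    y_true=y_true.copy(),
                )
            )
    return Dataset(
        experiments=experiments,
        input_names=model.input_names or None,
    )
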