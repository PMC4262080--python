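# Methods

## Setting

`nrhmc` does Bayesian parameter estimation for ODE models of biochemical
reaction networks observed **at steady state** under multiple constant
perturbations. The model class is

    dx/dt = f(x, rho, u),   x(0) = x0 known,   h(x) = C x + c0,

with molecular concentrations `x` (n states), strictly positive kinetic
parameters `rho` (m parameters) and an input vector `u` encoding the
experimental condition (knockdown level, ligand dose, ...). For each of the
`n_E` experiments the system is assumed to relax to a stable steady state
`xbar(theta, u_j)` before measurement; bifurcations and multistability are out
of scope. Observations are

    y_ij = h_i(xbar(theta, u_j)) + delta_ij,   delta_ij ~ N(0, sigma_ij^2),

with *known* noise scales `sigma_ij` (empirical replicate variances in
practice). Only the Gaussian noise model is implemented; the likelihood sits
behind a single assembly function so other noise models could be slotted in.

Because rates are positive, all inference happens in log space
`theta = log(rho)`. The transform is applied symbolically at model build time,
so every derivative the package produces already contains the chain-rule
factor `rho = exp(theta)`.

## Posterior and geometry

With a Gaussian prior N(mu, Xi) on `theta` the log-posterior is, up to the
evidence constant,

    log p(theta | y) = L(theta) + log p(theta),
    L(theta) = -1/2 sum_ij [ (y_ij - h_i(xbar_j))^2 / sigma_ij^2 + log(2 pi sigma_ij^2) ].

Normalisation constants are *kept* in the logged values so that likelihoods
are comparable across noise settings; they cancel in every acceptance ratio
and the evidence is never evaluated.

The key computational observation is that at a steady state the implicit
function theorem converts sensitivity analysis into linear algebra:

    J_f S = -df/dtheta                       (first order, S = dxbar/dtheta)
    J_f S2[:, r, s] = -(RHS from S and the second derivatives of f)

and both solves share one LU factorisation of `J_f(xbar)`. From `S` alone
follow the log-posterior gradient and the expected-Fisher-information metric

    G(theta) = sum_j (C S_j)^T diag(sigma_j)^-2 (C S_j) + Xi^-1,

which is symmetric positive definite thanks to the prior precision term (no
other regularisation is applied). From `S2` follow the metric derivatives
`dG/dtheta_k` needed by Riemannian samplers. No dynamic (ODE) sensitivity
integration appears anywhere.

### Conservation relations

Mass-action networks with conserved pools (e.g. total receptor) have a
singular Jacobian everywhere, so the linear solves above are impossible until
the model is reduced. `reduce_by_conservation` verifies each proposed linear
combination is conserved (its time derivative is symbolically zero),
eliminates one species per relation — preferring unobserved species so the
output map keeps its meaning — and folds the substitution through `f` and
through `C` (which may pick up a constant offset). Totals are fixed by the
known initial condition.

## Samplers

Three Metropolis kernels share a chain runner and a common geometry interface:

* **HMC** — Euclidean Hamiltonian dynamics with mass matrix `M` (identity by
  default), explicit kick-drift-kick leapfrog, acceptance
  `min(1, exp(-dH))`.
* **RMHMC** — the momentum covariance is the position-dependent metric
  `G(theta)`; the Hamiltonian gains `1/2 log det G + 1/2 eta' G^-1 eta` and
  the equations of motion become implicit. The generalised leapfrog solves
  the implicit half-kick and drift by fixed-point iteration (`fp_tol`,
  default 1e-8; `fp_max`, default 10). Non-convergence aborts the trajectory
  and the proposal is rejected, preserving Metropolis correctness.
* **SMMALA** — a one-step position-specific Langevin proposal
  `N(theta + eps^2/2 G^-1 grad, eps^2 G^-1)` with the full asymmetric
  Metropolis-Hastings correction.

Momentum is fully resampled every transition. Trajectory lengths carry a
±20% uniform jitter by default (`jitter=0.2`, switchable off) to avoid
resonance pathologies; the jitter draw is independent of the state, so
detailed balance is unaffected. A single seeded `numpy` generator owned by
the chain makes runs bit-for-bit reproducible from the configuration alone.

### Steady-state backends

Each kernel runs with either backend:

* `integration` (baseline): every geometry evaluation integrates the initial
  value problem from `x0` with LSODA until `||f||_inf` stays below tolerance
  (default 1e-8) over two geometrically growing reporting intervals. All
  experiments are stacked into one block-diagonal system so the solver is
  called once per evaluation.
* `newton` (tracking): the backend remembers the last successful evaluation
  (`theta_a`, steady states, sensitivities) and seeds a batched
  Newton-Raphson solve with the first-order prediction
  `xbar_a + S_a (theta - theta_a)`. Because Hamiltonian trajectories move in
  many small steps, the prediction is almost always inside the Newton basin
  and refinement takes a couple of iterations. Newton convergence means
  `||f||_inf <= 1e-9 (1 + ||x||_inf)` within 20 iterations; divergence
  (growing residual three times in a row), a singular Jacobian, or a
  negative converged concentration triggers a per-experiment fallback to
  integration. If that also fails the evaluation reports log-posterior
  `-inf` and the proposal is rejected. Chains always start from a full
  integration solve; within a trajectory there is no re-verification against
  integration (an interpretation choice — failures are caught by the
  fallback and by the Metropolis correction, and the backend-equivalence
  test below checks the net effect).

Negative concentrations at *intermediate* Newton iterates are permitted
(iterates are not trajectories); only the converged point is checked.

## Diagnostics

The integrated autocorrelation length `tau_int` of a scalar chain series
(conventionally the log-likelihood) is estimated with the Gamma-method:
normalised autocovariances are summed up to a window `W` chosen automatically
by the standard criterion `g(W) = exp(-W/tau_exp) - tau_exp/sqrt(W N) < 0`
with window parameter `S = 1.5`, plus the usual bias correction and the error
estimate `sigma(tau) ~ 2 tau sqrt((W + 1/2 - tau)/N)`. Under this convention
an uncorrelated series has `tau_int = 0.5`.

The effective sampling speed is defined as

    v = N / (2 tau_int t_E),

with `t_E` the post-burn-in wall-clock sampling time (burn-in and tuning are
excluded — a choice, since conventions differ). Only the relative speeds
`v_r = v / min(v)` are hardware independent; absolute values are reported but
never compared across machines.

For two-parameter models the exact posterior is evaluated on a regular grid
(normalised to the grid cell area) and compared with a Gaussian KDE of the
chain via total-variation distance. The KDE uses `scipy`'s Silverman-factor,
sample-covariance-scaled kernel rather than a per-axis bandwidth: the MAPK
posterior is a narrow diagonal ridge, and an axis-aligned kernel would smear
it by an order of magnitude across the ridge.

## Example models and synthetic data

The real perturbation datasets this class of analysis was developed on live
in third-party supplements and are not bundled; the fixtures emulate their
structure so that everything here runs download-free.

* `linear_toy` — `dx/dt = u - e^theta x`; closed forms for everything
  (`xbar = u e^-theta`, `S = -xbar`, `S2 = +xbar`). The oracle for unit
  tests.
* `mapk_erk` — distributive two-site Erk phosphorylation with total Erk
  `u = Erk_T` as the input and the phosphorylation rate multiplied by a
  negative-feedback factor `u/(1+u)`. Two parameters
  (`k_phos`, `k_dephos`); output is ppErk. The exact published rate
  equations were not available in the source text, so these equations are
  this package's own transcription of that model family; steady-state data
  identify only the ratio `k_phos/k_dephos`, giving the characteristic
  correlated ridge posterior. Design: 10 graded knockdown levels
  `Erk_T in {0.1, ..., 1.0}` including the `u = 1` control, `sigma = 0.2`
  (in normalised units), reference rates `(4, 1)`.
* `insulin_mma` — a minimal insulin receptor/IRS phosphorylation model:
  5 species with two conserved pools (receptor, substrate), reduced to
  3 states and 6 parameters; a synthetic stand-in that is structurally
  faithful (conservation relations, dose-response read-out, fixed output
  scale `C_{1,3} = 2.5` that is never sampled). The unreduced 5-species
  variant ships as `insulin_mma_full` to exercise the reduction machinery.
  Design: basal dose 0 plus 9 log-spaced doses over 1e-2..1e2, `sigma = 0.1`.
* `insulin_mifa` — a larger synthetic insulin model (6 reduced states,
  14 parameters) with receptor internalisation feeding IRS phosphorylation
  and a PKB-mediated negative feedback loop; `sigma = 0.15`.

`generate_dataset` solves the model at the design's true parameters
(integration plus Newton polish), applies the output map and adds Gaussian
noise of the design's scale; the noise-free outputs are kept alongside as
test oracles. `sigma = 0` yields a noise-free dataset for oracle use
(inference requires strictly positive scales). What the generator does *not*
emulate: replicate-dependent noise, systematic (blot-normalisation) errors,
missing observations, or model misspecification — so passing tests show
correctness of the machinery on well-specified models, not robustness to
real-data pathologies.

The default prior for all fixtures is N(0, 4 I) in log space (+/- 2 sigma
covers about 3.5 decades of each rate constant); informative-prior
experiments shrink selected diagonal entries.

## Numerical choices

* Steady-state integration: LSODA (stiff-capable) with analytic Jacobian;
  oracle-grade tolerances (rtol 1e-10..1e-12) for finite-difference tests,
  looser defaults (rtol 1e-8) inside samplers where Monte-Carlo noise
  dominates.
* Fixed-point iterations in the generalised leapfrog converge linearly with
  rate proportional to `eps`; step sizes around 0.1-0.2 with `fp_max` 10-20
  are reliable on the fixtures. The implicit equations are solved to
  `fp_tol` in the infinity norm, which bounds the reversibility defect of a
  trajectory by roughly `n_steps * fp_tol`.
* SMMALA step sizes around 1.0 (MAPK) and 0.35 (Mma) give acceptance rates
  near 0.9 and 0.6 respectively; `tune_epsilon` automates the pilot search.
* Credible-region coverage uses the Mahalanobis ellipsoid of the sample mean
  and covariance at the chi-squared quantile — adequate for the near-Gaussian
  ridge posteriors of the fixtures.
* Ties/degenerate inputs: constant series raise on autocorrelation
  estimation; zero-variance samples raise on KDE; `N = 0` chains are legal
  and empty.

## Problem sizes in the validation suite

The test suite and `scripts/acceptance.py` run on one core in minutes, with
sizes chosen as the package's own desk-scale study: sampler-correctness
checks on a 2-D correlated Gaussian at N = 20,000; MAPK backend-equivalence
chains at N = 10,000 (tests) / 6,000 (script) compared marginal-by-marginal
after thinning by twice the estimated `tau_int` (the two-sample KS test
assumes independent draws); grid resolutions of 150-220 over the region
holding essentially all posterior mass; effective-speed comparisons on Mma at
N = 1,200-1,500 per backend; coverage over 50 (tests) / 25 (script) synthetic
MAPK datasets with N = 5,000 / 3,000 chains. AR(1) series of length 1e6
validate the `tau_int` estimator against its closed form
`0.5 (1 + phi)/(1 - phi)`.

## Known limitations

* Steady-state tracking assumes the tracked fixed point varies smoothly along
  the trajectory; systems with bifurcations or coexisting attractors in the
  sampled parameter region are not supported.
* Only linear (affine after reduction) output maps and Gaussian noise.
* The Fisher metric uses the Gauss-Newton form; far from the data-supported
  region it can be dominated by the prior precision, where RMHMC loses its
  advantage over HMC.
* Wall-clock effective speeds depend on hardware and implementation detail;
  only their ratios on the same machine are meaningful, which is how they are
  used and tested here.
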