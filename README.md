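# nrhmc

**Newton-Raphson accelerated Hamiltonian Monte Carlo for steady-state ODE
models of biochemical networks.**

Systems biologists routinely fit reaction-network ODE models
`dx/dt = f(x, ρ, u)` to *steady-state perturbation data*: outputs
`y_ij = (C x̄(ρ, u_j))_i + noise` measured after the system has relaxed under
each experimental condition `u_j` (gene knockdowns, ligand doses). Such data
rarely identify all rate constants, so point estimation is inadequate and one
samples the Bayesian posterior over log-parameters `θ = log ρ` instead. The
bottleneck is that every Markov-chain step needs the steady states — and, for
gradient-based samplers, their parameter sensitivities.

`nrhmc` implements the whole pipeline and its key acceleration:

* **Samplers:** Hamiltonian Monte Carlo (HMC), Riemannian-manifold HMC
  (RMHMC, with the generalised leapfrog integrator), and the simplified
  manifold Metropolis-adjusted Langevin algorithm (SMMALA).
* **Geometry from linear algebra:** at a steady state, the sensitivities
  solve `J_f S = −∂f/∂θ` and a second linear system for
  `S2 = ∂²x̄/∂θ∂θ` with the *same* LU factorisation — no sensitivity ODEs.
  From `S` follow the log-posterior gradient and the metric tensor
  `G(θ) = Σ_j (C S_j)ᵀ diag(σ_j)⁻² (C S_j) + Ξ⁻¹` (expected Fisher
  information plus prior precision); from `S2` follow `∂G/∂θ`.
* **Two steady-state backends for every sampler:** `integration` (the
  baseline: re-integrate the ODE from `x0` at every evaluation) and `newton`
  (track the steady state along the trajectory: predict
  `x̄ + S Δθ`, refine by Newton-Raphson, fall back to integration on
  failure). Both target the same posterior; the Newton backend is typically
  one to two orders of magnitude faster per effective sample.
* **Symbolic model core:** models are written as plain text (states,
  parameters, inputs, rate expressions); all derivative bundles are derived
  symbolically once at build time, with log-parameterisation baked in.
  Conservation relations (which make `J_f` singular) are eliminated by
  `reduce_by_conservation`.
* **Diagnostics:** Γ-method integrated autocorrelation length `τ_int` with
  automatic windowing, effective sampling speed `v = N/(2 τ_int t_E)` and
  relative speeds, exact grid posteriors and KDE comparisons for
  two-parameter problems.
* **Fixtures:** an Erk-phosphorylation MAPK model (2 states / 2 parameters,
  knockdown design), two insulin-pathway models (3×6 and 6×14) with
  dose-response designs, a closed-form toy, and a synthetic steady-state
  data generator.

## Worked example

Generate a synthetic MAPK knockdown dataset (10 total-Erk levels, σ = 0.2) and
sample its posterior with Newton-tracking HMC:

```python
from nrhmc import SamplerConfig, run_chain, integrated_autocorrelation, fixtures

model   = fixtures.mapk_erk()
dataset = fixtures.generate_dataset(model, fixtures.mapk_design(seed=7))
prior   = fixtures.default_prior(model)          # N(0, 4 I) in log space

config = SamplerConfig(algorithm="hmc", backend="newton", eps=0.2, n_steps=20,
                       n_samples=2000, burn_in=300, seed=1)
chain = run_chain(model, dataset, prior, config)
```

Output of `python examples/02_sample_mapk_posterior.py`:

```
acceptance rate: 94.2%
posterior mean (log space): [ 0.59114677 -0.61339531]
true parameters:            [1.38629436 0.        ]
posterior sd:   [1.45423103 1.43937388]
tau_int = 1.78 +/- 0.25 (W=11, N=2000)
theta_1 - theta_2: 1.205 +/- 0.331 (true 1.386)
```

The marginals are wide (sd ≈ 1.45) because steady-state data identify only the
rate *ratio* `k_phos/k_dephos`: the combination `θ₁ − θ₂` is recovered tightly
(1.21 ± 0.33 against a true value of 1.39) while the sum follows the prior —
exactly the correlated-ridge situation Riemannian samplers are built for.

Comparing backends on the insulin model
(`python examples/03_backend_comparison.py`):

```
integration  acceptance 35.5%  tau_int 19.34  t_E 117.2 s  v 0.26/s
newton       acceptance 35.5%  tau_int 19.34  t_E 5.2 s  v 6.00/s
relative speed of NR-SMMALA vs SMMALA: 22.7x
```

Identical tuning and statistics — the Newton backend simply pays far less per
transition. `examples/04_grid_vs_kde.py` checks a chain against the exact
grid posterior (total-variation distance 0.043 at N = 6,000).

A thin CLI mirrors the library:

```bash
nrhmc simulate-data --model mapk_erk --design mapk --seed 7 --out mapk.tsv
nrhmc sample --model mapk_erk --data mapk.tsv --algorithm smmala \
      --backend newton --eps 1.0 --n 5000 --seed 1 --out chain.tsv
nrhmc diagnose chain.tsv
```

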