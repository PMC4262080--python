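"""Build a steady-state model and compute its sensitivities by linear algebra.

The Erk phosphorylation model has two states and two rate parameters; the
experimental input u is the total Erk amount.  Once the fixed point
f(xbar) = 0 is known, the first-order sensitivity S = dxbar/dtheta solves
J_f S = -df/dtheta — no sensitivity ODEs are ever integrated.
"""

import numpy as np

from nrhmc import solve_steady_state, fixtures

model = fixtures.mapk_erk()
theta = fixtures.theta_true("mapk_erk")  # log([k_phos, k_dephos]) = log([4, 1])
u = [1.0]  # the no-knockdown control: Erk_T = 1

res = solve_steady_state(model, theta, u)
print("states:", model.state_names)
print("steady state xbar:", res.xbar)
print("residual ||f(xbar)||:", res.residual_norm)
print("first-order sensitivity S = dxbar/dtheta:\n", res.S)
print("second-order S2 symmetric in (r, s):",
      np.allclose(res.S2, np.swapaxes(res.S2, 1, 2)))

# The doubly phosphorylated fraction rises with the phosphorylation rate and
# falls with the dephosphorylation rate, hence the sign pattern of S[1, :].
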