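"""Closed-form identities of the simulation populations.

Builds one cell of the Monte Carlo design and verifies, at exact population
moments, the quantities the design pins down analytically: the equal
loading implied by a composite reliability level, the Mode A weights, the
consistent reliability coefficient rho_A, and the explained variance of
each structural equation.
"""

import numpy as np

from regplsc import (
    DesignCell,
    build_population,
    estimate_weights_from_moments,
    fit_from_moments,
    implied_r2,
    loading_for_reliability,
    rho_A,
)
from regplsc.model_spec import coefficients_for_cell

cell = DesignCell(N=30, phi=0.4, reliability=0.8, r2=0.25)
pop = build_population(cell)
spec = pop.spec

lam = loading_for_reliability(cell.reliability, 4)
print(f"equal loading for reliability {cell.reliability} with 4 indicators: {lam:.5f}")
print("  (0.70711 = sqrt(0.5); each indicator shares half its variance with the factor)")

ws = estimate_weights_from_moments(pop.Sigma, spec)
print(f"population Mode A weight per indicator: {ws.weights['xi1'][0]:.5f}")
print("  (sqrt(0.1) ~ 0.31623: equal weights normalized to unit composite variance)")

block = [spec.indicators.index(i) for i in spec.blocks["xi1"]]
value, valid = rho_A(ws.weights["xi1"], pop.Sigma[np.ix_(block, block)])
print(f"rho_A at population moments: {value:.6f} (valid={valid})")
print("  (returns the design reliability exactly — the estimator is consistent)")

co = coefficients_for_cell(cell)
for eta in ("eta1", "eta2"):
    print(f"implied R^2 of {eta}: {implied_r2(spec, co, eta):.4f} (design level {cell.r2})")

res = fit_from_moments(pop.Sigma, spec, "plsc")
print("population PLSc path estimates (should equal the true coefficients):")
for lab, val in res.paths.coefficients.items():
    print(f"  {lab}: {val:+.4f} (truth {co[lab]:+.4f})")
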