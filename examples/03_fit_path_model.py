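"""Fit the packaged triticale path model to the packaged covariance fixture.

The fixture covariance is rebuilt from published per-variable variances and
the Pearson correlation matrix (n = 37): five observed variables — Ag(I) and
Cu(II) medium concentrations, CHH-context de novo methylation and sequence
variation percentages, and green plant regeneration efficiency (GPRE).  The
model has six directed paths, three exogenous covariances and two residuals
(df = 1).  Prints the ML estimates with standard errors and standardized
coefficients, the fit-index summary and the effect decomposition.
"""

from regenpath.datasets import triticale_moments, triticale_path_model
from regenpath.sem.effects import effects_decomposition
from regenpath.sem.fit import baseline_model, fit_ml
from regenpath.sem.indices import fit_indices

model = triticale_path_model()
moments = triticale_moments()
fit = fit_ml(model, moments)
print(f"converged: {fit.converged} after {fit.iterations} iterations")
print(f"chi2 = {fit.chi_square:.4f}, df = {fit.df}, p = {fit.p_value:.4f}\n")
print(fit.summary().round(4))

indices = fit_indices(fit.moments.S, fit, baseline_model(moments))
print("\nfit indices:")
print({k: round(v, 4) for k, v in indices.as_dict().items()})

print("\ndirect / indirect / total effects:")
print(effects_decomposition(fit).round(4))
print("\nNote: the fixture's source tables are internally rounded, so this "
      "refit is a demonstration; it will not reproduce the original "
      "coefficients digit-for-digit.")
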