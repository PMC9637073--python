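"""Descriptive statistics, correlations, OLS and LASSO on a synthetic table.

Builds a per-regenerant table (treatment covariates + simulated outcome
variables), then runs the pre-path-model statistical stages.  The summary-
statistic regression at the end uses only published-style means, variances
and a correlation, showing how a determination coefficient can be recovered
without raw data: with r = 0.807 it must equal r**2 = 0.65.
"""

from regenpath import stats as st
from regenpath.datasets import triticale_path_model, triticale_truth
from regenpath.simulate import simulate_sem_dataset

model = triticale_path_model()
data = simulate_sem_dataset(model, triticale_truth(), n=37, seed=5)

print("descriptive statistics (n=37 simulated regenerants):")
print(st.describe_table(data).round(3))

corr = st.pearson_matrix(data)
print("\nPearson correlations:")
print(corr.r.round(3))

fit = st.ols_fit(data["GPRE"], data[["Cu"]])
print(f"\nOLS: GPRE = {fit.intercept:.4f} + {fit.slopes['Cu']:.4f} * Cu,"
      f"  R^2 = {fit.r_squared:.3f}")

lasso = st.lasso_fit(data["GPRE"], data[["Cu", "Ag", "CHH_DNMV", "CHH_SV"]],
                     k_folds=5, seed=5)
print(f"\nLASSO: optimal lambda = {lasso.optimal_lambda:.6f}")
print("slopes:", {k: round(v, 4) for k, v in lasso.slopes.items()})

summary = st.ols_from_summary(mean_x=5.427, mean_y=2.556,
                              var_x=12.787, var_y=2.752, r=0.807, n=37)
print(f"\nfrom summary statistics alone: slope {summary.slopes['x']:.4f}, "
      f"intercept {summary.intercept:.4f}, R^2 {summary.r_squared:.3f}")
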