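# Methods

## The biological model and what is being estimated

Anther-culture regenerants are compared with their single donor plant, so any
marker difference is attributable to the in vitro passage (tissue-culture-
induced variation). Each locus is profiled twice: with Acc65I/MseI (Acc65I is
blocked by cytosine methylation in its GGTACC site) and with KpnI/MseI (KpnI
cuts the same site regardless of methylation). A change in the KpnI pattern
between donor and regenerant therefore indicates a change in the DNA sequence
itself, while an Acc65I change at a KpnI-constant locus indicates a
methylation change. The quantities carried forward are per-regenerant
percentages of sequence variation (SV), de novo methylation (DNMV) and
demethylation (DMV), per sequence context (CG, CHG, CHH); the CHH
(asymmetric) context is the analysis focus. The downstream question — how
Cu(II) and Ag(I) in the induction medium, and the variation they induce,
shape green plant regeneration efficiency (GPRE, green regenerants per 100
plated anthers) — is posed as a recursive path model over the five observed
variables Ag, Cu, CHH_DNMV (exogenous, freely covarying), CHH_SV and GPRE
(endogenous).

## metAFLP scoring

Band states are concatenated as (Acc65I donor, Acc65I regenerant, KpnI donor,
KpnI regenerant), giving 16 possible 4-digit codes. The published source of
the code-to-event table is not reproduced in the summary tables this package
ships, so the default table is derived from the platform semantics:

* any KpnI donor/regenerant difference (8 codes `xx10`, `xx01`) → **SV**;
* KpnI constant-present with Acc65I loss (`1011`) → **DNMV**, with Acc65I
  gain (`0111`) → **DMV**;
* `0000`, `1111` and the platform-constant codes `0011`, `1100` →
  **NO_CHANGE**;
* the two KpnI-absent single-platform changes (`0100`, `1000`) → **COMPLEX**
  (not attributable to a single event).

The table ships as a versioned CSV (`regenpath/data/event_classification.csv`)
and any total 16-row replacement can be supplied; all tests pin the shipped
default. Percentages use as denominator **all scorable codes in the context**
(including NO_CHANGE), which bounds every category at 100% and yields exactly
0% for a regenerant identical to its donor. A code with any missing band
state is excluded from numerator and denominator alike — no band state is
imputed. Treatment-level summaries are unweighted means over member
regenerants; the regression and LASSO stages default to regenerant-level
rows.

## Association statistics

Descriptives use the n−1 variance and the small-sample-adjusted
(Fisher–Pearson) skewness and adjusted excess kurtosis, the conventions of
the commercial suites this analysis style is usually run in. Correlation
p-values are two-sided t-tests with df = n−2. `ols_from_summary` reconstructs
a single-predictor fit from (means, variances, r) alone: slope =
r·√(var_y/var_x), R² = r². On the packaged summary values for GPRE on Cu(II)
(r = 0.807) this gives slope 0.3744, intercept 0.5242, R² = 0.651 — note the
printed regression equation circulating with these summaries has the two
coefficients transposed relative to what the summaries imply; the package
computes from the summaries and treats neither printed coefficient as ground
truth. LASSO minimises (1/2n)‖y − b₀ − Xb‖² + λΣ|bⱼ| by coordinate descent
(scikit-learn), with internal standardization and back-transformation,
10-fold seeded cross-validation on a 100-point log-spaced grid from λ_max
down to 10⁻⁴λ_max, and the mean-squared-error criterion.

## The ML path-model engine

Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ with B strictly acyclic (checked via networkx) and Ψ
holding a saturated exogenous block plus mutually uncorrelated residuals.
Identification is checked as df = p(p+1)/2 − q ≥ 0. The discrepancy
F(θ) = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p is minimised by a Levenberg–Marquardt
iteration: analytic ∂Σ/∂θ (for a path parameter, A∂B Σ + its transpose with
A = (I−B)⁻¹; for a Ψ parameter, A∂Ψ Aᵀ), gradient tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹)∂Σ],
curvature from the expected information 0.5·tr(Σ⁻¹∂ᵢΣ Σ⁻¹∂ⱼΣ). Damping uses
Marquardt diagonal scaling (H + μ·diag H) with the Nielsen gain-ratio
schedule (μ₀ = 10⁻³; shrink by max(1/3, 1−(2ρ−1)³) on success, grow
geometrically on rejection); steps that leave the positive-definite cone are
rejected. Convergence is declared on the Newton decrement ½gᵀH⁻¹g < 10⁻¹⁰
(scale-invariant, so one tolerance covers path and variance parameters),
with a cap of 500 iterations; a short BFGS run on the analytic gradient then
polishes the solution, because the expected information overstates curvature
when the model does not fit exactly and can leave estimates a few 10⁻⁶ short
of the optimum. Start values: zero paths, exogenous block taken from S,
residuals at half the sample variances; on non-convergence, up to five
seeded jittered restarts. Non-convergence is flagged on the result — never
silently accepted — and any non-positive variance estimate attaches an
explicit Heywood-case warning.

Conventions (configurable where noted): sample covariance divisor N−1 and
χ² = (N−1)·F_min (divisor N available as an option); standard errors from
the inverse expected information of the log-likelihood, matching the
"critical ratio" output of the mainstream SEM packages; standardized
estimates use model-implied standard deviations (required for the direct +
indirect = total identity to hold on the standardized scale). The
independence baseline is closed-form: χ²_b = −(N−1)·ln|R|, df_b = p(p−1)/2.
Fit indices follow the standard definitions; RMSEA uses
√(max(χ²−df, 0)/(df·(N−1))). For the df = 1 fixture model, no common RMSEA
variant reproduces the originally printed value from its own printed χ²; the
formula here is documented, not tuned. Note on terminology: this engine
covers *recursive* (acyclic) models only — the class the fixture model
belongs to, despite the "non-recursive" wording that sometimes accompanies
it.

A useful oracle, used throughout the tests: for any acyclic model with a
saturated exogenous block and uncorrelated residuals, the normal likelihood
factorises equation-by-equation, so the ML path estimates equal
per-equation OLS of each endogenous variable on its parents, computed from
S. The engine is required to agree with this closed form to 10⁻⁶ on random
models.

## Synthetic data: what it emulates and what it does not

`simulate_design` reproduces the 8-treatment layout (Cu ∈ {0.1, 5, 10} µM,
Ag ∈ {0, 10, 60} µM, incubation ∈ {35, 42, 49} d) with group sizes 3–6
summing to 37 regenerants; the per-treatment composition is not part of the
published summary tables, so the defaults were fixed once to span the factor
grid, with the highest-copper/silver-free condition carrying the largest
group. `simulate_sem_dataset` draws i.i.d. multivariate normal observations
from Σ(θ*); the packaged truth θ* is the published coefficient vector, whose
implied covariance is positive definite. `simulate_metaflp` plants marginal
event rates (defaults: the published CHH means, SV 8.65%, DNMV 0.58%, DMV
0.76%) on a configurable marker panel (default 183/196/218 markers for
CG/CHG/CHH, 597 in all). The donor KpnI band is present by default at every
locus; the donor Acc65I band is present with probability 0.6 (the
donor-band-frequency default, chosen as a plausible mid-range value and
configurable). Because a DNMV event is writable only at donor-unmethylated
loci and DMV only at donor-methylated loci, conditional per-locus
probabilities are inflated by the corresponding locus-class frequency so
the *marginal* planted rates are unbiased; COMPLEX codes require KpnI-absent
donor loci and are off by default.

Deliberate simplifications: marker-by-regenerant events are independent (no
linkage, no marker correlation, no per-treatment rate heterogeneity); the
outcome draws are exactly multivariate normal, whereas real GPRE and
percentage variables are bounded and mildly skewed. Passing round-trip and
recovery tests therefore certifies the *estimators* (scoring inverts the
generative code-writing exactly; the ML engine recovers generating
parameters with calibrated Wald intervals), not the distributional
robustness of either on real field data.

## Problem sizes and numerical checks

The test suite and acceptance script use: 2,000 CHH markers × 37 regenerants
for the planted-rate round trip (exact-binomial 99% reference intervals);
N = 5,000 for single-replicate parameter recovery (all 14 parameters within
3 Wald SE); 500 replicates at N = 200 for interval coverage (mean 95% Wald
coverage required in [0.92, 0.98]); 50 random acyclic models (p ≤ 6) for the
OLS-oracle equivalence. These sizes give the Monte-Carlo resolution the
corresponding assertions need while keeping a full run in tens of seconds.

## Known limitations

* The packaged covariance fixture is rebuilt from rounded published
  variances and correlations, and those summaries are not perfectly
  consistent with the originally reported ML estimates (e.g. the Cu variance
  differs between the descriptive table and the ML table, and one reported
  test statistic does not equal its estimate/SE ratio). A refit on the
  reconstruction therefore lands near, but not on, the original
  coefficients; the package asserts internal identities and simulation-based
  properties instead of digit-level equality.
* Latent variables, mean structures, multi-group models, GLS/ADF estimators,
  modification indices and bootstrap SEs are out of scope.
* Scoring assumes the two platform matrices are aligned on identical marker
  panels; fragment sizing and band calling from gel images are upstream of
  this package.
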