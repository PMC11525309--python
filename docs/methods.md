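# Methods

## The power model

For an *M*-estimator, `√n(ϑ̂ₙ − ϑ₀) → N(0, H⁻¹IH⁻¹)`, where `H` is the
expected Hessian of the objective and `I` the variance of the scores.
The z-value of the focal entry j, `z = ϑ̂ₙⱼ / SE(ϑ̂ₙⱼ)` with
`SE = sqrt((H⁻¹IH⁻¹)ⱼⱼ / n)`, is then approximately normal with unit
variance and mean `√n·ϑ₀ⱼ/ψ`, `ψ = sqrt((H⁻¹IH⁻¹)ⱼⱼ)`. Writing the
one-sided rejection probability through the standard normal CDF gives

    P(S = 1 | n) = Φ(−q₁₋α + |ϑ₀ⱼ|/ψ · √n),

a probit model in √n with asymptotic coefficients
`β₀ = −q₁₋α`, `β₁ = |ϑ₀ⱼ|/ψ`. Both coefficients are **estimated freely**
from the simulated decisions — the asymptotic values hold only in the
large-n, large-R limit, and fixing β₀ would import the asymptotic
approximation into finite-sample fits. The deviation `β̂₀ − (−q₁₋α)` is
reported as a diagnostic (`PowerModelFit.intercept_diagnostic`).

For the two-sided test (equivalently the one-parameter Wald test) the
rejection probability has two terms,

    P(S = 1 | n) = Φ(β₀ + β₁√n) + Φ(β₀ − β₁√n),

which is not a GLM mean function under any standard link; its likelihood
is maximized directly with a β₁ ≥ 0 box constraint, seeded from the
one-sided probit fit. A boundary solution β₁ = 0 is flagged. The
comparison methods from the simulation-literature lineage — probit or
logit link with n or √n as predictor, and four-point linear
interpolation ("naive") — are retained so their bias relative to the
probit-√n model can be demonstrated.

### Inversion

Point estimate: `N_α = ⌈((link⁻¹(ρ) − β̂₀)/β̂₁)²⌉` for √n predictors
(no square for n predictors); the Wald variant inverts its monotone mean
function by integer bisection. If the solution falls at or below n = 1
the method returns 1. Values of ρ above .99 are refused: near-saturated
power rates carry extreme uncertainty in the inverse and are not
practically relevant.

Lower bound: `N_lb` is the smallest n at which the 1−α_ρ confidence-band
lower bound of predicted power reaches ρ, found by bisection on n over
[1, 10⁷] to 10⁻⁶ on the power scale, then rounded up and floored at
N_α. The point prediction at that n, `ρ̂_lb`, is reported. For the
probit-√n model this numerical search coincides with the algebraic
plug-in of ρ̂_lb into the closed-form inversion (asserted in tests); the
search generalizes to the Wald and naive curves where no closed form
exists.

### Confidence bands

Probit/logit bands are computed on the linear predictor
(`var(η̂) = x'Vx` with V the coefficient covariance from the inverse
observed information) and mapped through the response function; the
monotone map preserves coverage and keeps the band inside [0, 1]. The
Wald curve uses a probability-scale delta method with clipping, since
its two-term mean function has no invertible linear predictor. The
naive method attaches a Wald normal-approximation interval
`p̂ ± z₁₋α_ρ/₂ sqrt(p̂(1−p̂)/Rⱼ)` to each grid point (clipped, no
continuity correction) and interpolates bounds linearly.

### Degenerate inputs

Separation (all decisions identical, or outcomes perfectly ordered by
sample size) is detected before fitting and raised as a typed error
naming the remedy — widen the simulated n-range so the power curve is
straddled. Non-converged replications carry no significance information
and are always dropped (count reported). Repeated n values are pooled in
all parametric fits; the naive method requires exactly four distinct n.

## The simulation engine

### Analysis models

Linear SEM in the standard matrix form
`Σ(θ) = Λ(I−B)⁻¹Ψ(I−B)⁻ᵀΛ' + Θ` with four latent variables
(ξ₁, ξ₂, η₁, η₂), three indicators each, marker identification (first
loading of each latent fixed to 1 — consistent with the generating
loadings [1, .8, .7]), diagonal Θ, and no mean structure (data are
centered at the sample mean; double mean centering of product
indicators removes the need for intercepts).

Estimation minimizes `F_ML = log|Σ| + tr(SΣ⁻¹) − log|S| − p` (S with
divisor n). Each free parameter's `∂Σ/∂θⱼ` is a symmetric rank-two
outer product, which makes the analytic gradient, the casewise scores
and the information products O(p) per parameter; optimization is
L-BFGS-B on the analytic gradient with a Newton/step-halving polish
until the gradient norm is below 10⁻⁶. Convergence additionally
requires a positive-definite implied covariance and non-negative
variance estimates; failures are classified (max-iterations, non-PD,
Heywood) and excluded from power fits with their rate reported. A run
aborts if more than half the replications fail.

Standard errors: "naive" from the inverse observed information of the
casewise log-likelihood (Hessian by central finite differences of the
analytic gradient); "robust" from the sandwich `A⁻¹BA⁻¹` with B the sum
of casewise score outer products — the MLR-style variant that remains
valid when the data are not normal. Start values are automated:
loadings from marker-scaled covariances, structural paths from OLS on
marker proxies, variances from proxy residuals.

Latent interactions use the unconstrained product-indicator approach:
matched pairs of indicators are mean-centered, multiplied, and the
products centered again (exactly zero sample mean); the interaction
factor is measured by these products (marker fixed to 1), covaries
freely with the exogenous factors, and enters the structural model
through one new path. No nonlinear constraints are imposed. The UPI
model is misspecified even under normal ξ — hence robust standard
errors are the default for interaction studies.

### Data generation

The generator emulates two populations sharing one measurement design
(loadings [1, .8, .7] per latent, independent normal indicator
residuals):

    linear:  η₁ = .2ξ₁ + .5ξ₂ + ζ₁
             η₂ = .3η₁ + .4ξ₁ + .3ξ₂ + ζ₂
    interaction: adds .1·ξ₁ξ₂ to the η₁ equation

Residual variances of ζ₁, ζ₂ are solved analytically so all four latent
variables have unit variance; for centered normal ξ the product term is
uncorrelated with the linear terms and `Var(ξ₁ξ₂) = 1 + φ₁₂²`, giving
e.g. `Var(ζ₁) = 1 − (.04 + .25 + .10 + .0125) = .5975` at φ₁₂ = .5.
Under non-normal ξ the product-moment terms involve sixth-order cross
moments of the transform and are evaluated by a fixed-seed 10⁶-draw
Monte-Carlo step (documented fallback; the linear-term moments remain
analytic).

Parameters that matter:

- `phi12` — correlation of the exogenous latents. It is not derivable
  from the structural coefficients; the library default is .5 and the
  CLI requires it explicitly.
- `theta_residuals` — indicator residual variances, default .36 each,
  giving composite reliability ω = 2.5²/(2.5² + 3·.36) ≈ .853. A
  reliability pair (ω = .85 together with maximal reliability H = .88)
  is not attainable with equal residuals under these loadings, so the
  equal-residual default is documented as approximate and the vector is
  configurable per indicator.
- Kurtosis arguments are **excess** kurtosis everywhere (the convention
  of the Vale–Maurelli literature); a normal target is (0, 0).

Non-normality is generated by the Vale–Maurelli construction: per
variable a Fleishman cubic `Y = a + bZ + cZ² + dZ³` (a = −c, unit
variance) solved by Newton iteration to moment residual < 10⁻¹⁰, plus a
pairwise cubic solve for the pre-transform ("intermediate") correlation
matrix, which must be positive definite — no silent nearest-PD
smoothing is applied. Feasibility is enforced: targets outside the
cubic's attainable (skew, excess-kurtosis) region are rejected with a
typed error. Notably, skewness 2.3 cannot be paired with excess
kurtosis 6.5 — the cubic's kurtosis floor at that skewness is ≈ 7.26 —
so demonstration configurations pair 2.3 with 7.5. The transform can be
applied to the latent predictors (interaction studies) or, for the
linear model only, to the indicators themselves against the
model-implied indicator correlation matrix.

What the generator does **not** emulate: the Vale–Maurelli construction
has a normal copula, so only a narrow slice of non-normal dependence
structures is covered; there are no ordinal/categorical indicators, no
missing data, and no mean structure. Passing tests therefore
demonstrate calibration under these stylized populations, not under
arbitrary real data.

## Study orchestration and evaluation

Sample sizes are allocated by cycling an integer grid (R = k·gridsize
gives each size k times) or by a four-point split with the remainder at
the smallest size. Each replication draws its data from the i-th
spawned substream of the master seed, so results are bit-reproducible
and independent of execution order. Empirical reference power is the
relative frequency of significance among converged replications with an
exact Clopper–Pearson interval; reference grids are 50, 70, ..., 650
(31 sizes) for the linear model and 150, 200, ..., 1200 (22 sizes) for
the interaction model. Method evaluation across repeated studies
reports bias and RMSE of N̂_α, bias of predicted power at the reference
N, and the undershoot frequency `P(N̂_lb < N_α)` — the type-I proxy for
the lower-bound rule, expected near α_ρ/2. The type-I harness for the
z-test itself nulls the focal parameter explicitly in the generating
model.

## Problem sizes used in tests and the acceptance script

Calibration of the lower-bound rule uses 2,000 idealized studies
(Bernoulli decisions from a known probit truth, R = 550 each);
coefficient-recovery suites use R = 10⁵ decision logs; band coverage
uses 1,000 studies; moment targets use 10⁶ draws; the z-test level uses
1,000 ML fits at n = 500; sandwich/information agreement uses 200 fits
at n = 1,000. These sizes keep Monte-Carlo error well inside the
asserted tolerances while remaining desk-scale. Full-fidelity
references at 10⁶ replications per sample size are out of scope for the
shipped suites; `estimate_reference_power` supports arbitrary R_ref for
users who want them.

## Known limitations

- The probit-√n link is an asymptotic approximation: for estimators
  whose finite-sample distribution is far from normal on the simulated
  n-range (e.g. indirect effects in small samples) the fitted curve and
  the derived sample sizes inherit that approximation error. The
  intercept diagnostic helps detect this.
- Power modeling for the likelihood-ratio test is deliberately not
  provided — the probit-√n relationship does not hold for the LRT under
  non-normality.
- `N_lb` bisection assumes the band lower bound is nondecreasing in n;
  with extremely noisy fits (slope not significantly positive) the
  search reports non-achievability rather than extrapolating.
- The naive baseline cannot extrapolate outside its four-point grid and
  raises typed errors instead of guessing.
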