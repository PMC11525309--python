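# mspe — model-implied simulation-based power estimation for the z-test

Sample-size planning for models without closed-form power solutions —
latent-variable models, models fitted under distributional
misspecification, and generally any model estimated by an *M*-estimator
(ML, quasi-ML, least squares, GMM, ...). For such estimators the
parameter estimates are asymptotically normal with sandwich covariance
`H⁻¹ I H⁻¹`, so the z-value of a focal parameter ϑ₀ has approximate mean
`√n · |ϑ₀| / ψ`, where `ψ = sqrt((H⁻¹ I H⁻¹)_jj)` is the per-√n scale of
its standard error. The probability of a significant one-sided z-test at
level α is therefore approximately

```
P(significant | n) = Φ(−q₁₋α + |ϑ₀|/ψ · √n)
```

which is exactly a **probit regression of the binary significance
decision on √n**. `mspe` exploits this: simulate R datasets across a
range of sample sizes, record each replication's significance decision,
fit the probit-on-√n model by maximum likelihood, and invert it for the
required sample size at a target power ρ:

```
N_α = ⌈((Φ⁻¹(ρ) − β̂₀)/β̂₁)²⌉
```

Because the fitted curve itself carries Monte-Carlo uncertainty, the
package also reports a calibrated lower-bound sample size `N_lb`: the
smallest n whose 1−α_ρ confidence-band lower bound reaches ρ. Across
repeated simulation studies, `N_lb` undershoots the true requirement
with probability ≈ α_ρ/2 — planning with `N_lb` protects against
recommending a sample that is too small.

The package ships:

- **`mspe.power_model`** — probit-on-√n fitting, the two-sided (Wald)
  variant `Φ(β₀+β₁√n) + Φ(β₀−β₁√n)`, comparison curves (probit/logit on
  n or √n), a naive four-point linear-interpolation baseline, confidence
  bands, and both inversions (`required_n`, `required_n_lb`).
- **`mspe.sem_engine`** — a self-contained normal-theory ML fitter for
  linear SEM with naive and sandwich (robust/MLR-style) standard errors,
  z-tests, and the unconstrained product-indicator (UPI) machinery for
  latent interaction effects (matched, double-mean-centered products).
- **`mspe.synthetic_data`** — data generation for the two demonstration
  populations: a four-factor linear SEM (structural effects
  .2/.5/.3/.4/.3, loadings [1, .8, .7], standardized latents) and its
  interaction extension (effect .1), under multivariate normality or
  Vale–Maurelli non-normality (Fleishman cubics + intermediate
  correlation solve).
- **`mspe.study_runner`** — study orchestration (sample-size allocation,
  seeded substreams, decision logging), empirical reference power with
  exact binomial intervals, and bias/RMSE/type-I evaluation metrics.
- **`mspe.cli_io`** — CSV/JSON I/O and the `mspe` command-line tool
  (`simulate`, `fit-power`, `solve-n`, `reference`, `evaluate`,
  `report`).

## Worked example

Estimate the sample size needed for 80% power on the structural effect
γ₁₁ = .2 (ξ₁ → η₁) in the four-factor linear SEM, from R = 550
simulated replications with n spread uniformly over 51..600:

```python
from mspe import (GenerationConfig, StudyConfig, UniformAllocation,
                  run_power_study)

config = StudyConfig(
    generation=GenerationConfig(model="linear_sem", phi12=0.5),
    focal_label="gamma11", test="two-sided", alpha=0.05,
    rho=0.80, alpha_rho=0.05,
    R=550, allocation=UniformAllocation(51, 600),
    master_seed=12345, methods=("probit_sqrt", "wald_sqrt"),
)
result = run_power_study(config)
print(f"non-convergence rate: {result.nonconvergence_rate:.3f}")
for method, fit in result.fits.items():
    res = result.sample_sizes[method]
    print(f"{method}: beta0={fit.beta0:.3f}, beta1={fit.beta1:.4f}, "
          f"N_alpha={res.N_alpha}, N_lb={res.N_lb}, rho_hat_lb={res.rho_hat_lb:.3f}")
```

Output:

```
non-convergence rate: 0.005
probit_sqrt: beta0=-1.824, beta1=0.1642, N_alpha=264, N_lb=294, rho_hat_lb=0.839
wald_sqrt: beta0=-1.828, beta1=0.1644, N_alpha=264, N_lb=292, rho_hat_lb=0.836
```

Reading: the fitted power curve implies that n = 264 reaches 80% power
for the two-sided z-test on γ₁₁; accounting for the simulation
uncertainty of the curve itself, n = 294 guarantees it with
confidence 97.5% (the point prediction at that n is 83.9%). Only 0.5%
of replications failed to converge and were excluded from the fit.

The same pipeline runs from the shell:

```bash
mspe simulate --config study.json --out records.csv
mspe fit-power --records records.csv --method probit_sqrt --alpha 0.05 --out fit.json
mspe solve-n --fit fit.json --rho 0.8 --alpha-rho 0.05
```

For a latent interaction effect, set `model="qisem"` in the generation
config and fit with product indicators:

```python
from mspe import (build_upi_spec, fit_ml, linear_sem_spec,
                  make_product_indicators, z_test)
pairs = (("x1", "x4"), ("x2", "x5"), ("x3", "x6"))
data = make_product_indicators(dataset, pairs)
fit = fit_ml(data, build_upi_spec(linear_sem_spec(), pairs), robust=True)
print(z_test(fit, "gamma13", robust=True))
```

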