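"""Simulation of indicator data from the two study models.

Two structural models are supported, sharing the same measurement design
(four latent variables, three indicators each, loadings [1, .8, .7]):

* ``linear_sem``:   eta1 = g11*xi1 + g12*xi2 + zeta1
                    eta2 = b21*eta1 + g21*xi1 + g22*xi2 + zeta2
* ``qisem``: adds a latent interaction g13*xi1*xi2 to the eta1 equation.

Latent residual variances are solved so that every latent variable has unit
variance; exogenous latents are standard normal or, for distributional
misspecification, generated by the Vale-Maurelli approach (per-variable
Fleishman cubic polynomials of normals plus an intermediate-correlation
solve).  Kurtosis arguments are EXCESS kurtosis throughout (the convention
of the Vale-Maurelli literature): a normal variable has excess kurtosis 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConfigurationError, FeasibilityError

__all__ = [
    "NonNormalSpec",
    "GenerationConfig",
    "fleishman_coefficients",
    "fleishman_moments",
    "vm_intermediate_correlation",
    "vm_generate",
    "solve_standardizing_residuals",
    "generate_latents",
    "generate_indicators",
    "generate_dataset",
    "INDICATOR_COLUMNS",
]

INDICATOR_COLUMNS = ("x1", "x2", "x3", "x4", "x5", "x6", "y1", "y2", "y3", "y4", "y5", "y6")

# fixed seed for the documented Monte-Carlo fallback used when closed-form
# moments of transformed (non-normal) latents are unavailable
_MOMENT_MC_SEED = 202_406_171
_MOMENT_MC_N = 1_000_000


def fleishman_moments(coef: Sequence[float]) -> tuple[float, float, float, float]:
    """(mean, variance, skewness, excess kurtosis) of a + bZ + cZ^2 + dZ^3.

    Closed-form moment identities for a cubic polynomial of a standard
    normal; used both to solve for coefficients and as their own check.
    """
    a, b, c, d = coef
    mean = a + c
    var = b * b + 6 * b * d + 2 * c * c + 15 * d * d
    skew = 2 * c * (b * b + 24 * b * d + 105 * d * d + 2)
    exkurt = 24 * (
        b * d
        + c * c * (1 + b * b + 28 * b * d)
        + d * d * (12 + 48 * b * d + 141 * c * c + 225 * d * d)
    )
    return mean, var, skew / var ** 1.5 if var > 0 else np.nan, exkurt / var ** 2 if var > 0 else np.nan


def fleishman_coefficients(skew: float, exkurt: float) -> tuple[float, float, float, float]:
    """Solve for (a, b, c, d) with a = -c giving mean 0, variance 1 and the
    target skewness / excess kurtosis.

    Raises ``FeasibilityError`` outside the feasible region
    (approximately exkurt >= skew^2 - 2).
    """
    if exkurt < skew * skew - 2:
        raise FeasibilityError(
            f"(skew={skew}, excess kurtosis={exkurt}) lies outside the "
            "feasible region of the cubic transform (need exkurt >= skew^2 - 2)"
        )

    def residual(x: np.ndarray) -> np.ndarray:
        b, c, d = x
        return np.array(
            [
                b * b + 6 * b * d + 2 * c * c + 15 * d * d - 1.0,
                2 * c * (b * b + 24 * b * d + 105 * d * d + 2) - skew,
                24
                * (
                    b * d
                    + c * c * (1 + b * b + 28 * b * d)
                    + d * d * (12 + 48 * b * d + 141 * c * c + 225 * d * d)
                )
                - exkurt,
            ]
        )

    best = None
    starts = [[b0, 0.15 * skew, d0] for b0 in (1.0, 0.9, 0.7, 0.5, 0.3)
              for d0 in (0.0, 0.05, 0.15, 0.3)]
    for x0 in starts:
        sol = optimize.root(residual, x0, method="hybr", tol=1e-13)
        res_norm = float(np.abs(residual(sol.x)).max())
        if (best is None or res_norm < best[1]) and sol.x[0] > 0:
            best = (sol.x, res_norm)
        if best is not None and best[1] < 1e-10:
            break
    x, res_norm = best if best is not None else (np.zeros(3), np.inf)
    if res_norm >= 1e-10:
        raise FeasibilityError(
            f"no cubic transform attains (skew={skew}, excess kurtosis={exkurt}): "
            f"best moment residual {res_norm:.2e}. The pair may lie outside the "
            "transform's true feasible region even if it satisfies the "
            "approximate bound; restart from targets with higher kurtosis"
        )
    b, c, d = (float(v) for v in x)
    return (-c, b, c, d)


def _vm_pair_corr(r_target: float, ci: Sequence[float], cj: Sequence[float]) -> float:
    """Pre-polynomial correlation reproducing ``r_target`` after transform."""
    _, bi, c2i, di = ci
    _, bj, c2j, dj = cj
    k1 = bi * bj + 3 * bi * dj + 3 * di * bj + 9 * di * dj
    k2 = 2 * c2i * c2j
    k3 = 6 * di * dj
    roots = np.roots([k3, k2, k1, -r_target])
    real = roots[np.abs(roots.imag) < 1e-10].real
    real = real[(real >= -1.0) & (real <= 1.0)]
    if len(real) == 0:
        raise FeasibilityError(
            f"no intermediate correlation in [-1, 1] reproduces target r={r_target}"
        )
    # pick the root closest to the target (the relevant branch of the cubic)
    return float(real[np.argmin(np.abs(real - r_target))])


def vm_intermediate_correlation(
    target_corr: np.ndarray, fleishman: Sequence[Sequence[float]]
) -> np.ndarray:
    """Solve the pairwise Vale-Maurelli cubics for the pre-transform
    correlation matrix, and verify it is positive definite."""
    target_corr = np.asarray(target_corr, dtype=float)
    k = target_corr.shape[0]
    inter = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            inter[i, j] = inter[j, i] = _vm_pair_corr(
                target_corr[i, j], fleishman[i], fleishman[j]
            )
    eigmin = np.linalg.eigvalsh(inter).min()
    if eigmin <= 1e-10:
        raise FeasibilityError(
            f"intermediate correlation matrix is not positive definite "
            f"(smallest eigenvalue {eigmin:.3e}); no smoothing is applied"
        )
    return inter


@dataclass(frozen=True)
class NonNormalSpec:
    """Per-variable moment targets and solved transform for VM generation."""

    skew: tuple[float, ...]
    exkurt: tuple[float, ...]
    target_corr: np.ndarray
    fleishman: tuple[tuple[float, float, float, float], ...]
    intermediate_corr: np.ndarray

    @classmethod
    def build(
        cls,
        skew: Sequence[float],
        exkurt: Sequence[float],
        target_corr: np.ndarray,
    ) -> "NonNormalSpec":
        if len(skew) != len(exkurt):
            raise ConfigurationError("skew and exkurt must have equal length")
        coef = tuple(fleishman_coefficients(s, k) for s, k in zip(skew, exkurt))
        inter = vm_intermediate_correlation(np.asarray(target_corr, float), coef)
        return cls(
            skew=tuple(float(s) for s in skew),
            exkurt=tuple(float(k) for k in exkurt),
            target_corr=np.asarray(target_corr, dtype=float),
            fleishman=coef,
            intermediate_corr=inter,
        )


def vm_generate(spec: NonNormalSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n rows of correlated non-normal variables (mean 0, variance 1)."""
    chol = np.linalg.cholesky(spec.intermediate_corr)
    z = rng.standard_normal((n, len(spec.skew))) @ chol.T
    out = np.empty_like(z)
    for j, (a, b, c, d) in enumerate(spec.fleishman):
        zj = z[:, j]
        out[:, j] = a + zj * (b + zj * (c + zj * d))
    return out


@dataclass(frozen=True)
class GenerationConfig:
    """Population model for data generation.

    ``gamma13`` is the latent interaction effect (0 in ``linear_sem``; the
    study value for ``qisem`` is .1).  ``phi12`` is the correlation of the
    exogenous latents; it is not derivable from the structural coefficients
    and must be chosen explicitly (default .5).  ``theta_residuals`` are the
    twelve indicator residual variances (default .36 each, giving omega
    ~= .85 with loadings [1, .8, .7]).  ``nonnormal_target`` chooses whether
    the Vale-Maurelli transform is applied to the latent predictors or to
    the indicators (the latter only for ``linear_sem``).
    """

    model: Literal["linear_sem", "qisem"] = "linear_sem"
    gamma11: float = 0.2
    gamma12: float = 0.5
    gamma13: float | None = None
    beta21: float = 0.3
    gamma21: float = 0.4
    gamma22: float = 0.3
    phi12: float = 0.5
    loadings: tuple[float, float, float] = (1.0, 0.8, 0.7)
    theta_residuals: tuple[float, ...] = (0.36,) * 12
    distribution: Literal["normal", "vale_maurelli"] = "normal"
    nonnormal: NonNormalSpec | None = None
    nonnormal_target: Literal["latent", "manifest"] = "latent"
    n: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in ("linear_sem", "qisem"):
            raise ConfigurationError(f"unknown model {self.model!r}")
        if self.gamma13 is None:
            object.__setattr__(
                self, "gamma13", 0.1 if self.model == "qisem" else 0.0
            )
        if self.model == "linear_sem" and self.gamma13 != 0.0:
            raise ConfigurationError("linear_sem requires gamma13 = 0")
        if len(self.theta_residuals) != 12:
            raise ConfigurationError("theta_residuals must have 12 entries")
        if any(t < 0 for t in self.theta_residuals):
            raise ConfigurationError("indicator residual variances must be >= 0")
        if self.distribution == "vale_maurelli" and self.nonnormal is None:
            raise ConfigurationError(
                "vale_maurelli distribution requires a NonNormalSpec"
            )
        if (
            self.distribution == "vale_maurelli"
            and self.nonnormal_target == "manifest"
            and self.model != "linear_sem"
        ):
            raise ConfigurationError(
                "manifest-level non-normality is only supported for linear_sem"
            )


def _xi_moments(config: GenerationConfig) -> dict[str, float]:
    """Moments of (xi1, xi2, xi1*xi2) needed for residual-variance solving.

    Under normality these are closed-form (Isserlis); under latent
    Vale-Maurelli non-normality the product moments involve sixth-order
    cross moments of the transform and are obtained by a fixed-seed
    Monte-Carlo evaluation at n = 10^6 (documented fallback).
    """
    phi = config.phi12
    if config.distribution == "normal" or config.nonnormal_target == "manifest":
        return {
            "m11": phi,           # E[xi1 xi2]
            "v_int": 1 + phi * phi,  # Var(xi1 xi2)
            "c_int1": 0.0,        # Cov(xi1 xi2, xi1)
            "c_int2": 0.0,
        }
    rng = np.random.default_rng(_MOMENT_MC_SEED)
    xi = vm_generate(config.nonnormal, _MOMENT_MC_N, rng)
    prod = xi[:, 0] * xi[:, 1]
    return {
        "m11": float(np.mean(prod)),
        "v_int": float(np.var(prod)),
        "c_int1": float(np.cov(prod, xi[:, 0])[0, 1]),
        "c_int2": float(np.cov(prod, xi[:, 1])[0, 1]),
    }


def solve_standardizing_residuals(config: GenerationConfig) -> tuple[float, float]:
    """Latent residual variances (Var(zeta1), Var(zeta2)) that standardize
    eta1 and eta2 to unit variance.

    Under normality: Var(zeta1) = 1 - [g11^2 + g12^2 + 2 g11 g12 phi
    + g13^2 (1 + phi^2)] (the centered product term is uncorrelated with the
    linear terms), and Var(zeta2) analogously via the implied covariances
    Cov(eta1, xi_k).  Raises if the systematic variance reaches 1.
    """
    g11, g12, g13 = config.gamma11, config.gamma12, config.gamma13
    b21, g21, g22 = config.beta21, config.gamma21, config.gamma22
    mom = _xi_moments(config)
    m11, v_int = mom["m11"], mom["v_int"]
    c1, c2 = mom["c_int1"], mom["c_int2"]

    sys1 = (
        g11 * g11
        + g12 * g12
        + 2 * g11 * g12 * m11
        + g13 * g13 * v_int
        + 2 * g13 * (g11 * c1 + g12 * c2)
    )
    if sys1 >= 1:
        raise ConfigurationError(
            f"systematic variance of eta1 is {sys1:.4f} >= 1; cannot standardize"
        )
    var_z1 = 1.0 - sys1

    cov_e1_x1 = g11 + g12 * m11 + g13 * c1
    cov_e1_x2 = g12 + g11 * m11 + g13 * c2
    sys2 = (
        b21 * b21
        + g21 * g21
        + g22 * g22
        + 2 * b21 * g21 * cov_e1_x1
        + 2 * b21 * g22 * cov_e1_x2
        + 2 * g21 * g22 * m11
    )
    if sys2 >= 1:
        raise ConfigurationError(
            f"systematic variance of eta2 is {sys2:.4f} >= 1; cannot standardize"
        )
    return var_z1, 1.0 - sys2


def generate_latents(
    config: GenerationConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw latent scores (xi1, xi2, eta1, eta2) for n cases.

    The interaction term enters the eta1 equation as the raw product
    xi1*xi2 (the model carries no mean structure; fitted models center the
    data, so the product's nonzero mean under correlated xi is immaterial).
    """
    var_z1, var_z2 = solve_standardizing_residuals(config)
    phi = config.phi12
    if config.distribution == "normal" or config.nonnormal_target == "manifest":
        chol = np.linalg.cholesky(np.array([[1.0, phi], [phi, 1.0]]))
        xi = rng.standard_normal((n, 2)) @ chol.T
    else:
        xi = vm_generate(config.nonnormal, n, rng)
    zeta = rng.standard_normal((n, 2))
    xi1, xi2 = xi[:, 0], xi[:, 1]
    eta1 = (
        config.gamma11 * xi1
        + config.gamma12 * xi2
        + config.gamma13 * xi1 * xi2
        + math.sqrt(var_z1) * zeta[:, 0]
    )
    eta2 = (
        config.beta21 * eta1
        + config.gamma21 * xi1
        + config.gamma22 * xi2
        + math.sqrt(var_z2) * zeta[:, 1]
    )
    return pd.DataFrame({"xi1": xi1, "xi2": xi2, "eta1": eta1, "eta2": eta2})


def generate_indicators(
    latents: pd.DataFrame,
    loadings: Sequence[float],
    theta_residuals: Sequence[float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Measurement model x = Lambda * latent + delta with diagonal Theta.

    Column order: x1-x3 measure xi1, x4-x6 measure xi2, y1-y3 measure eta1,
    y4-y6 measure eta2; within each block the loadings follow ``loadings``.
    """
    if len(loadings) != 3:
        raise ConfigurationError("three loadings per latent are required")
    theta = np.asarray(theta_residuals, dtype=float)
    if len(theta) != 12:
        raise ConfigurationError("theta_residuals must have 12 entries")
    if np.any(theta < 0):
        raise ConfigurationError("indicator residual variances must be >= 0")
    n = len(latents)
    lat = latents[["xi1", "xi2", "eta1", "eta2"]].to_numpy()
    lam = np.asarray(loadings, dtype=float)
    noise = rng.standard_normal((n, 12)) * np.sqrt(theta)
    data = np.empty((n, 12))
    for k in range(4):
        data[:, 3 * k : 3 * k + 3] = lat[:, [k]] * lam + noise[:, 3 * k : 3 * k + 3]
    return pd.DataFrame(data, columns=list(INDICATOR_COLUMNS))


def _manifest_vm_dataset(
    config: GenerationConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Indicator-level non-normality: VM applied to the twelve indicators
    with the model-implied indicator correlation matrix as target."""
    var_z1, var_z2 = solve_standardizing_residuals(config)
    g11, g12 = config.gamma11, config.gamma12
    b21, g21, g22 = config.beta21, config.gamma21, config.gamma22
    phi = config.phi12
    # latent covariance matrix of (xi1, xi2, eta1, eta2); all unit variance
    c_e1_x1 = g11 + g12 * phi
    c_e1_x2 = g12 + g11 * phi
    c_e2_x1 = b21 * c_e1_x1 + g21 + g22 * phi
    c_e2_x2 = b21 * c_e1_x2 + g22 + g21 * phi
    c_e2_e1 = b21 + g21 * c_e1_x1 + g22 * c_e1_x2
    sigma_l = np.array(
        [
            [1.0, phi, c_e1_x1, c_e2_x1],
            [phi, 1.0, c_e1_x2, c_e2_x2],
            [c_e1_x1, c_e1_x2, 1.0, c_e2_e1],
            [c_e2_x1, c_e2_x2, c_e2_e1, 1.0],
        ]
    )
    lam = np.zeros((12, 4))
    for k in range(4):
        lam[3 * k : 3 * k + 3, k] = config.loadings
    sigma_x = lam @ sigma_l @ lam.T + np.diag(config.theta_residuals)
    sd = np.sqrt(np.diag(sigma_x))
    corr_x = sigma_x / np.outer(sd, sd)
    if len(config.nonnormal.skew) != 12:
        raise ConfigurationError(
            "manifest-level non-normality requires one (skew, exkurt) pair "
            "per indicator (12 values)"
        )
    # re-solve the intermediate correlation against the model-implied
    # indicator correlations (the user-supplied target matrix is ignored here)
    spec = NonNormalSpec.build(config.nonnormal.skew, config.nonnormal.exkurt, corr_x)
    data = vm_generate(spec, n, rng) * sd
    return pd.DataFrame(data, columns=list(INDICATOR_COLUMNS))


def generate_dataset(
    config: GenerationConfig,
    n: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a full indicator dataset from the configured population model.

    Identical (config, seed) pairs yield bit-identical datasets.
    """
    n = config.n if n is None else n
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if config.distribution == "vale_maurelli" and config.nonnormal_target == "manifest":
        return _manifest_vm_dataset(config, n, rng)
    latents = generate_latents(config, n, rng)
    return generate_indicators(latents, config.loadings, config.theta_residuals, rng)
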