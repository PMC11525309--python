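"""Parametric power-curve models for the z-test and their sample-size inversion.

The central idea: across R simulated replications, the binary significance
decision S_i of a z-test at sample size n_i follows (asymptotically) a probit
model with sqrt(n) as the predictor,

    P(S_i = 1 | n_i) = Phi(beta0 + beta1 * sqrt(n_i)),

with asymptotic coefficients beta0 = -q_{1-alpha} and beta1 = |theta0| / psi,
where psi is the per-sqrt(n) scale of the focal parameter's standard error.
Fitting this probit regression to a significance-decision log pools the
information across all simulated sample sizes; inverting the fitted curve
yields the required sample size N_alpha for a target power rho, and the
confidence band around the fitted curve yields a calibrated lower-bound
sample size N_lb with P(N_lb < N_alpha) ~= alpha_rho / 2.

Alternative curve models kept for comparison: the two-sided (Wald) variant
with mean function Phi(b0 + b1*sqrt(n)) + Phi(b0 - b1*sqrt(n)), probit/logit
with n or sqrt(n) as predictor, and a naive four-point linear interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from .errors import (
    ExtrapolationError,
    GridError,
    InvalidEffectError,
    InversionError,
    NotAchievableError,
    PowerCapError,
    SeparationError,
)

__all__ = [
    "SignificanceRecord",
    "EffectSpec",
    "PowerModelFit",
    "PowerPrediction",
    "SampleSizeResult",
    "analytic_power",
    "fit_power_model",
    "fit_wald_power_model",
    "fit_naive",
    "predict_power",
    "required_n",
    "required_n_lb",
    "PARAMETRIC_METHODS",
]

POWER_CAP = 0.99
N_SEARCH_MAX = 10_000_000
PARAMETRIC_METHODS = ("probit_sqrt", "wald_sqrt", "probit_n", "logit_sqrt", "logit_n")

MethodTag = Literal["probit_sqrt", "wald_sqrt", "probit_n", "logit_sqrt", "logit_n", "naive"]


@dataclass(frozen=True)
class SignificanceRecord:
    """One simulated replication's z-test outcome at sample size ``n``.

    Replications that did not converge carry no significance information and
    are excluded from every power fit (their count is reported).
    """

    n: int
    significant: int
    converged: int = 1
    replicate_id: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"sample size must be >= 1, got {self.n}")
        if self.significant not in (0, 1):
            raise ValueError(f"significant must be 0 or 1, got {self.significant}")
        if self.converged not in (0, 1):
            raise ValueError(f"converged must be 0 or 1, got {self.converged}")


@dataclass(frozen=True)
class EffectSpec:
    """Analytic description of a focal effect for the z-test.

    Parameters
    ----------
    theta0 : float
        Population value of the focal parameter (model units).
    avar_factor : float
        psi = sqrt((H^-1 I H^-1)_{jj}), the per-sqrt(n) scale of the standard
        error: SE(theta_hat) = avar_factor / sqrt(n).
    sided : {"one-sided", "two-sided"}
    alpha : float
        Test level in (0, 1).
    """

    theta0: float
    avar_factor: float
    sided: Literal["one-sided", "two-sided"] = "one-sided"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.avar_factor > 0:
            raise InvalidEffectError(
                f"avar_factor must be positive, got {self.avar_factor}"
            )
        if not 0 < self.alpha < 1:
            raise InvalidEffectError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.sided not in ("one-sided", "two-sided"):
            raise InvalidEffectError(f"unknown sidedness {self.sided!r}")


@dataclass
class PowerModelFit:
    """A fitted power-curve model.

    For the parametric methods ``beta0``/``beta1`` are the ML coefficients of
    the binary-response model and ``vcov`` their 2x2 covariance (inverse
    observed information).  For ``naive`` only ``naive_table`` is populated:
    rows (n_j, R_j, p_hat_j, lb_j, ub_j) at the four grid points, bands at
    level 1 - ``naive_alpha_rho``.
    """

    method: MethodTag
    alpha: float
    beta0: float | None = None
    beta1: float | None = None
    vcov: np.ndarray | None = None
    naive_table: pd.DataFrame | None = None
    naive_alpha_rho: float | None = None
    n_records: int = 0
    dropped_nonconverged: int = 0
    converged: bool = True
    boundary: bool = False

    def intercept_diagnostic(self) -> float | None:
        """Deviation of beta0 from its asymptotic value -q_{1-alpha}.

        Large deviations signal that the z-test's finite-sample behaviour
        departs from the asymptotic normal regime on the simulated n-range.
        """
        if self.beta0 is None:
            return None
        if self.method == "wald_sqrt":
            ref = -stats.norm.ppf(1 - self.alpha / 2)
        else:
            ref = -stats.norm.ppf(1 - self.alpha)
        return self.beta0 - ref


@dataclass(frozen=True)
class PowerPrediction:
    """Predicted power at a sample size with a 1 - alpha_rho confidence band."""

    n: float
    rho_hat: float
    lb: float
    ub: float
    alpha_rho: float


@dataclass(frozen=True)
class SampleSizeResult:
    """Point and lower-bound required sample sizes for a target power rho.

    ``rho_hat_lb`` is the predicted power at the sample size whose band lower
    bound equals rho; it always lies at or above rho.
    """

    rho: float
    N_alpha: int
    N_lb: int
    rho_hat_lb: float
    method: MethodTag


# ---------------------------------------------------------------------------
# link / predictor helpers

def _predictor(method: str, n: np.ndarray | float) -> np.ndarray | float:
    if method in ("probit_sqrt", "logit_sqrt", "wald_sqrt"):
        return np.sqrt(n)
    return np.asarray(n, dtype=float) if isinstance(n, np.ndarray) else float(n)


def _link_inv(method: str, eta):
    if method.startswith("probit") or method == "wald_sqrt":
        return special.ndtr(eta)
    return special.expit(eta)


def _link(method: str, p: float) -> float:
    if method.startswith("probit"):
        return float(stats.norm.ppf(p))
    return float(special.logit(p))


def _wald_mean(beta0: float, beta1: float, sqrt_n) -> np.ndarray | float:
    return special.ndtr(beta0 + beta1 * np.asarray(sqrt_n)) + special.ndtr(
        beta0 - beta1 * np.asarray(sqrt_n)
    )


def _coerce_records(
    records: Sequence[SignificanceRecord] | pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Return (n, significant) arrays of converged records and the drop count."""
    if isinstance(records, pd.DataFrame):
        n = records["n"].to_numpy(dtype=float)
        s = records["significant"].to_numpy(dtype=float)
        conv = (
            records["converged"].to_numpy(dtype=bool)
            if "converged" in records.columns
            else np.ones(len(records), dtype=bool)
        )
    else:
        records = list(records)
        n = np.array([r.n for r in records], dtype=float)
        s = np.array([r.significant for r in records], dtype=float)
        conv = np.array([bool(r.converged) for r in records])
    dropped = int((~conv).sum())
    return n[conv], s[conv], dropped


def _check_separation(g: np.ndarray, s: np.ndarray) -> None:
    if s.min() == s.max():
        which = "significant" if s[0] == 1 else "non-significant"
        raise SeparationError(
            f"all decisions are {which}; the likelihood has no interior maximum. "
            "Widen the simulated sample-size range so both outcomes occur."
        )
    g1, g0 = g[s == 1], g[s == 0]
    if g1.min() >= g0.max() or g0.min() >= g1.max():
        raise SeparationError(
            "outcomes are perfectly ordered by sample size (complete/quasi "
            "separation); ML coefficients diverge. Widen the simulated "
            "sample-size range so the power curve is straddled."
        )


# ---------------------------------------------------------------------------
# operations

def analytic_power(effect: EffectSpec, n: float) -> float:
    """Asymptotic power of the z-test at sample size ``n``.

    One-sided: Phi(-q_{1-alpha} + |theta0|/psi * sqrt(n)).  Two-sided adds the
    (usually negligible) opposite-tail term:
    Phi(-q_{1-alpha/2} + mu) + Phi(-q_{1-alpha/2} - mu) with
    mu = |theta0|/psi * sqrt(n).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    mu = abs(effect.theta0) / effect.avar_factor * math.sqrt(n)
    if effect.sided == "one-sided":
        q = stats.norm.ppf(1 - effect.alpha)
        return float(special.ndtr(-q + mu))
    q = stats.norm.ppf(1 - effect.alpha / 2)
    return float(special.ndtr(-q + mu) + special.ndtr(-q - mu))


def fit_power_model(
    records: Sequence[SignificanceRecord] | pd.DataFrame,
    method: MethodTag = "probit_sqrt",
    alpha: float = 0.05,
) -> PowerModelFit:
    """Fit a binary-response model to a significance-decision log by ML.

    ``method`` chooses link (probit/logit) and predictor (sqrt(n) or n);
    ``wald_sqrt`` and ``naive`` dispatch to their dedicated fitters.
    Non-converged records are dropped before fitting and counted in
    ``dropped_nonconverged``.
    """
    if method == "wald_sqrt":
        return fit_wald_power_model(records, alpha=alpha)
    if method == "naive":
        return fit_naive(records, alpha_rho=alpha)
    if method not in ("probit_sqrt", "probit_n", "logit_sqrt", "logit_n"):
        raise ValueError(f"unknown power-model method {method!r}")

    n, s, dropped = _coerce_records(records)
    if len(np.unique(n)) < 2:
        raise ValueError("need converged records at >= 2 distinct sample sizes")
    g = np.asarray(_predictor(method, n))
    _check_separation(g, s)

    exog = np.column_stack([np.ones_like(g), g])
    model_cls = sm.Probit if method.startswith("probit") else sm.Logit
    model = model_cls(s, exog)
    converged = True
    try:
        res = model.fit(method="newton", maxiter=100, disp=0, warn_convergence=False)
        converged = bool(res.mle_retvals.get("converged", True))
        beta = np.asarray(res.params, dtype=float)
        vcov = np.asarray(res.cov_params(), dtype=float)
    except (np.linalg.LinAlgError, optimize.OptimizeWarning, RuntimeError):
        converged = False
        beta = np.array([np.nan, np.nan])
        vcov = np.full((2, 2), np.nan)
    vcov = (vcov + vcov.T) / 2.0
    return PowerModelFit(
        method=method,
        alpha=alpha,
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        vcov=vcov,
        n_records=len(n),
        dropped_nonconverged=dropped,
        converged=converged,
    )


def _wald_negloglik(beta: np.ndarray, sqrt_n: np.ndarray, s: np.ndarray) -> float:
    p = np.clip(_wald_mean(beta[0], beta[1], sqrt_n), 1e-12, 1 - 1e-12)
    return float(-(s * np.log(p) + (1 - s) * np.log1p(-p)).sum())


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    k = len(x)
    H = np.empty((k, k))
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * steps[i] * steps[j])
    return H


def fit_wald_power_model(
    records: Sequence[SignificanceRecord] | pd.DataFrame,
    alpha: float = 0.05,
) -> PowerModelFit:
    """Fit the two-sided (one-parameter Wald test) power-curve variant.

    Mean function P(S=1|n) = Phi(b0 + b1*sqrt(n)) + Phi(b0 - b1*sqrt(n)),
    with b1 constrained >= 0.  No standard GLM link has this form, so the
    likelihood is maximized directly (quasi-Newton, seeded from the
    one-sided probit fit); vcov is the inverse observed information.
    """
    n, s, dropped = _coerce_records(records)
    if len(np.unique(n)) < 2:
        raise ValueError("need converged records at >= 2 distinct sample sizes")
    sqrt_n = np.sqrt(n)
    _check_separation(sqrt_n, s)

    probit = fit_power_model(
        pd.DataFrame({"n": n, "significant": s, "converged": 1}),
        method="probit_sqrt",
        alpha=alpha,
    )
    x0 = np.array([probit.beta0, max(probit.beta1, 1e-3)])
    res = optimize.minimize(
        _wald_negloglik,
        x0,
        args=(sqrt_n, s),
        method="L-BFGS-B",
        bounds=[(None, None), (0.0, None)],
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    beta = res.x
    boundary = bool(beta[1] <= 1e-12)
    H = _numeric_hessian(lambda b: _wald_negloglik(b, sqrt_n, s), beta)
    try:
        vcov = np.linalg.inv(H)
        vcov = (vcov + vcov.T) / 2.0
    except np.linalg.LinAlgError:
        vcov = np.full((2, 2), np.nan)
    return PowerModelFit(
        method="wald_sqrt",
        alpha=alpha,
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        vcov=vcov,
        n_records=len(n),
        dropped_nonconverged=dropped,
        converged=bool(res.success),
        boundary=boundary,
    )


def fit_naive(
    records: Sequence[SignificanceRecord] | pd.DataFrame,
    alpha_rho: float = 0.05,
) -> PowerModelFit:
    """Four-point linear-interpolation baseline.

    Records must fall on exactly four distinct sample sizes.  Per grid point:
    p_hat_j = mean(S) with a normal-approximation interval
    p_hat_j +/- z_{1-alpha_rho/2} * sqrt(p_hat_j (1 - p_hat_j) / R_j), clipped
    to [0, 1].  Power and its band between grid points are the piecewise
    linear interpolants.
    """
    n, s, dropped = _coerce_records(records)
    grid = np.unique(n)
    if len(grid) != 4:
        raise GridError(
            f"naive method requires exactly 4 distinct sample sizes, got {len(grid)}"
        )
    z = stats.norm.ppf(1 - alpha_rho / 2)
    rows = []
    for nj in grid:
        sj = s[n == nj]
        rj = len(sj)
        p = sj.mean()
        half = z * math.sqrt(p * (1 - p) / rj)
        rows.append(
            {
                "n": nj,
                "R": rj,
                "p_hat": p,
                "lb": max(0.0, p - half),
                "ub": min(1.0, p + half),
            }
        )
    table = pd.DataFrame(rows)
    return PowerModelFit(
        method="naive",
        alpha=alpha_rho,
        naive_table=table,
        naive_alpha_rho=alpha_rho,
        n_records=len(n),
        dropped_nonconverged=dropped,
        converged=True,
    )


def _naive_interp(table: pd.DataFrame, n: float, col: str) -> float:
    grid = table["n"].to_numpy()
    if n < grid[0] or n > grid[-1]:
        raise ExtrapolationError(
            f"n={n} is outside the naive grid [{grid[0]:g}, {grid[-1]:g}]; "
            "linear interpolation does not extrapolate"
        )
    return float(np.interp(n, grid, table[col].to_numpy()))


def predict_power(
    fit: PowerModelFit, n: float, alpha_rho: float = 0.05
) -> PowerPrediction:
    """Predicted power at ``n`` with a 1 - alpha_rho confidence band.

    Probit/logit bands are built on the linear-predictor scale and mapped
    through the monotone response function (keeps bounds in [0, 1]);
    the Wald variant uses a probability-scale delta method with clipping;
    the naive method interpolates its per-grid-point intervals.
    """
    if not fit.converged:
        raise InversionError("power-model fit did not converge; cannot predict")
    if fit.method == "naive":
        rho = _naive_interp(fit.naive_table, n, "p_hat")
        lb = _naive_interp(fit.naive_table, n, "lb")
        ub = _naive_interp(fit.naive_table, n, "ub")
        return PowerPrediction(
            n=n,
            rho_hat=rho,
            lb=min(lb, rho),
            ub=max(ub, rho),
            alpha_rho=fit.naive_alpha_rho if fit.naive_alpha_rho is not None else alpha_rho,
        )

    z = stats.norm.ppf(1 - alpha_rho / 2)
    if fit.method == "wald_sqrt":
        srt = math.sqrt(n)
        p = float(_wald_mean(fit.beta0, fit.beta1, srt))
        up, um = fit.beta0 + fit.beta1 * srt, fit.beta0 - fit.beta1 * srt
        grad = np.array(
            [
                stats.norm.pdf(up) + stats.norm.pdf(um),
                srt * (stats.norm.pdf(up) - stats.norm.pdf(um)),
            ]
        )
        var = float(grad @ fit.vcov @ grad)
        half = z * math.sqrt(max(var, 0.0))
        return PowerPrediction(
            n=n,
            rho_hat=p,
            lb=max(0.0, p - half),
            ub=min(1.0, p + half),
            alpha_rho=alpha_rho,
        )

    g = float(_predictor(fit.method, n))
    x = np.array([1.0, g])
    eta = fit.beta0 + fit.beta1 * g
    se_eta = math.sqrt(max(float(x @ fit.vcov @ x), 0.0))
    rho = float(_link_inv(fit.method, eta))
    lb = float(_link_inv(fit.method, eta - z * se_eta))
    ub = float(_link_inv(fit.method, eta + z * se_eta))
    return PowerPrediction(n=n, rho_hat=rho, lb=lb, ub=ub, alpha_rho=alpha_rho)


def _check_rho(rho: float, alpha: float) -> None:
    if rho > POWER_CAP:
        raise PowerCapError(
            f"target power {rho} exceeds the evaluation cap {POWER_CAP}; "
            "power rates above .99 are not supported"
        )
    if rho <= alpha:
        raise ValueError(f"target power {rho} must exceed the test level {alpha}")


def _bisect_smallest_n(
    curve, rho: float, n_max: int = N_SEARCH_MAX, n_min: int = 1
) -> int:
    """Smallest integer n in [n_min, n_max] with curve(n) >= rho, for a
    nondecreasing curve."""
    if curve(n_max) < rho:
        raise NotAchievableError(
            f"power curve does not reach {rho} within n <= {n_max}"
        )
    lo, hi = n_min, n_max  # invariant: curve(hi) >= rho
    if curve(lo) >= rho:
        return n_min
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if curve(mid) >= rho:
            hi = mid
        else:
            lo = mid
    return hi


def required_n(fit_or_effect: PowerModelFit | EffectSpec, rho: float) -> int:
    """Required sample size N_alpha for target power ``rho`` (ceiling inversion).

    probit/logit on sqrt(n): N = ceil(((link^-1(rho) - b0)/b1)^2); on n the
    square is dropped.  The Wald variant and two-sided effect specs use
    monotone bisection of their two-term mean function; the naive method
    takes the first crossing of its interpolated polyline.
    """
    if isinstance(fit_or_effect, EffectSpec):
        eff = fit_or_effect
        _check_rho(rho, eff.alpha)
        if eff.theta0 == 0:
            raise InversionError("null effect: power never exceeds the test level")
        b1 = abs(eff.theta0) / eff.avar_factor
        if eff.sided == "one-sided":
            b0 = -stats.norm.ppf(1 - eff.alpha)
            x = (stats.norm.ppf(rho) - b0) / b1
            return 1 if x <= 1 else int(math.ceil(x * x - 1e-9))
        return _bisect_smallest_n(lambda m: analytic_power(eff, m), rho)

    fit = fit_or_effect
    _check_rho(rho, fit.alpha)
    if fit.method == "naive":
        table = fit.naive_table
        if table["p_hat"].max() < rho:
            raise NotAchievableError(
                f"interpolated power never reaches {rho} within the naive grid"
            )
        return _bisect_smallest_n(
            lambda m: _naive_interp(table, m, "p_hat"),
            rho,
            n_max=int(table["n"].max()),
            n_min=int(table["n"].min()),
        )
    if not fit.converged:
        raise InversionError("power-model fit did not converge; cannot invert")
    if fit.beta1 is None or fit.beta1 <= 0:
        raise InversionError(
            f"fitted slope beta1={fit.beta1} is not positive; the power curve "
            "cannot be inverted for a required sample size"
        )
    if fit.method == "wald_sqrt":
        return _bisect_smallest_n(
            lambda m: float(_wald_mean(fit.beta0, fit.beta1, math.sqrt(m))), rho
        )
    target = _link(fit.method, rho)
    x = (target - fit.beta0) / fit.beta1
    if x <= 1:
        return 1  # the fitted curve already exceeds rho at n = 1
    # the 1e-9 slack absorbs round-trip float error in link^-1(link(rho))
    if fit.method in ("probit_sqrt", "logit_sqrt"):
        return int(math.ceil(x * x - 1e-9))
    return int(math.ceil(x - 1e-9))


def required_n_lb(
    fit: PowerModelFit, rho: float, alpha_rho: float = 0.05
) -> SampleSizeResult:
    """Lower-bound-calibrated required sample size N_lb.

    Finds the smallest n whose 1 - alpha_rho band lower bound reaches rho
    (bisection on n, tolerance 1e-6 on the power scale), so that
    P(N_lb < N_alpha) ~= alpha_rho / 2 across repeated simulation studies.
    For the naive method the per-grid lower bounds are interpolated and the
    first crossing taken.
    """
    N_alpha = required_n(fit, rho)

    if fit.method == "naive":
        table = fit.naive_table
        if table["lb"].max() < rho:
            raise NotAchievableError(
                f"band lower bound never reaches {rho} within the naive grid"
            )
        n_lb = _bisect_smallest_n(
            lambda m: _naive_interp(table, m, "lb"),
            rho,
            n_max=int(table["n"].max()),
            n_min=int(table["n"].min()),
        )
        n_lb = max(n_lb, N_alpha)
        rho_hat = _naive_interp(table, n_lb, "p_hat")
        return SampleSizeResult(
            rho=rho, N_alpha=N_alpha, N_lb=n_lb, rho_hat_lb=rho_hat, method="naive"
        )

    def lb(m: float) -> float:
        return predict_power(fit, m, alpha_rho=alpha_rho).lb

    lo, hi = 1.0, float(N_SEARCH_MAX)
    if lb(hi) < rho:
        raise NotAchievableError(
            f"confidence-band lower bound never reaches {rho} within "
            f"n <= {N_SEARCH_MAX}; increase R or the simulated n-range"
        )
    if lb(lo) >= rho:
        n_star = lo
    else:
        while True:
            mid = 0.5 * (lo + hi)
            val = lb(mid)
            if abs(val - rho) < 1e-6:
                n_star = mid
                break
            if (hi - lo) < 1e-9 * max(1.0, hi):
                n_star = hi
                break
            if val >= rho:
                hi = mid
            else:
                lo = mid
    N_lb = max(int(math.ceil(n_star - 1e-9)), N_alpha)
    rho_hat_lb = predict_power(fit, n_star, alpha_rho=alpha_rho).rho_hat
    return SampleSizeResult(
        rho=rho, N_alpha=N_alpha, N_lb=N_lb, rho_hat_lb=rho_hat_lb, method=fit.method
    )
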