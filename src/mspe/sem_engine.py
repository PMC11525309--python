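"""Normal-theory ML estimation of linear structural equation models.

Covariance-structure models in the usual matrix form: with latent vector
f = (exogenous..., endogenous...), loading matrix Lambda (p x m), structural
matrix B (strictly lower triangular in the latent ordering), latent
covariance pattern Psi (exogenous covariances and structural residual
variances) and indicator residual pattern Theta,

    Sigma(theta) = Lambda (I - B)^-1 Psi (I - B)^-T Lambda' + Theta.

Estimation minimizes the ML discrepancy
F(theta) = log|Sigma| + tr(S Sigma^-1) - log|S| - p (data centered at the
sample mean; no mean structure).  Standard errors come from the inverse
observed information of the casewise log-likelihood ("naive") or from the
sandwich H^-1 I H^-1 with I estimated by casewise score outer products
("robust", the MLR-style variant valid under distributional
misspecification).  The z-test for a focal parameter divides its estimate
by the chosen standard error.

Latent interactions are handled by the unconstrained product-indicator
approach: matched, double-mean-centered products of indicators measure the
interaction factor, and the augmented model is fitted with the same linear
ML machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import SEMSpecError

__all__ = [
    "SEMSpec",
    "FitResult",
    "ZTestResult",
    "linear_sem_spec",
    "implied_moments",
    "fit_ml",
    "z_test",
    "make_product_indicators",
    "build_upi_spec",
]

_GRAD_TOL = 1e-6


@dataclass
class SEMSpec:
    """Matrix-form specification of a linear SEM.

    ``lam``, ``b``, ``psi``, ``theta`` hold fixed values; the ``*_free``
    boolean masks mark free entries (symmetric matrices are masked on the
    lower triangle only).  ``labels`` maps a parameter name to its matrix
    location; every free entry has exactly one label.
    """

    latent_names: list[str]
    indicator_names: list[str]
    lam: np.ndarray
    lam_free: np.ndarray
    b: np.ndarray
    b_free: np.ndarray
    psi: np.ndarray
    psi_free: np.ndarray
    theta: np.ndarray
    theta_free: np.ndarray
    labels: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    focal_label: str | None = None

    def __post_init__(self) -> None:
        m, p = len(self.latent_names), len(self.indicator_names)
        if self.lam.shape != (p, m) or self.b.shape != (m, m):
            raise SEMSpecError("matrix dimensions do not match latent/indicator counts")
        if np.any(np.triu(self.b_free) | (np.triu(self.b) != 0)):
            raise SEMSpecError("structural matrix must be strictly lower triangular")
        self._params: list[tuple[str, str, int, int]] = []
        loc_to_label = {v: k for k, v in self.labels.items()}
        for mat_name, free in (
            ("lam", self.lam_free),
            ("b", self.b_free),
            ("psi", self.psi_free),
            ("theta", self.theta_free),
        ):
            idx = np.argwhere(free)
            for i, j in idx:
                if mat_name in ("psi", "theta") and j > i:
                    raise SEMSpecError(
                        f"symmetric matrix {mat_name} must be masked on the "
                        "lower triangle"
                    )
                label = loc_to_label.get(
                    (mat_name, int(i), int(j)), f"{mat_name}[{i},{j}]"
                )
                self.labels.setdefault(label, (mat_name, int(i), int(j)))
                self._params.append((label, mat_name, int(i), int(j)))
        if self.focal_label is not None and self.focal_label not in self.labels:
            raise SEMSpecError(f"focal label {self.focal_label!r} is not a parameter")

    @property
    def n_free(self) -> int:
        return len(self._params)

    @property
    def param_labels(self) -> list[str]:
        return [p[0] for p in self._params]

    def matrices(
        self, theta_vec: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Materialize (Lambda, B, Psi, Theta) at a free-parameter vector."""
        if len(theta_vec) != self.n_free:
            raise SEMSpecError(
                f"parameter vector has length {len(theta_vec)}, expected {self.n_free}"
            )
        lam, b = self.lam.copy(), self.b.copy()
        psi, th = self.psi.copy(), self.theta.copy()
        mats = {"lam": lam, "b": b, "psi": psi, "theta": th}
        for val, (_, mat, i, j) in zip(theta_vec, self._params):
            mats[mat][i, j] = val
            if mat in ("psi", "theta") and i != j:
                mats[mat][j, i] = val
        return lam, b, psi, th

    def to_dict(self) -> dict:
        """JSON-serializable form: each matrix as a list of entries
        {row, col, free, value, label}."""
        out: dict = {
            "latent_names": list(self.latent_names),
            "indicator_names": list(self.indicator_names),
            "focal_label": self.focal_label,
            "matrices": {},
        }
        loc_to_label = {v: k for k, v in self.labels.items()}
        for name, mat, free in (
            ("lam", self.lam, self.lam_free),
            ("b", self.b, self.b_free),
            ("psi", self.psi, self.psi_free),
            ("theta", self.theta, self.theta_free),
        ):
            entries = []
            sym = name in ("psi", "theta")
            for i in range(mat.shape[0]):
                cols = range(i + 1) if sym else range(mat.shape[1])
                for j in cols:
                    if free[i, j] or mat[i, j] != 0:
                        entries.append(
                            {
                                "row": int(i),
                                "col": int(j),
                                "free": bool(free[i, j]),
                                "value": float(mat[i, j]),
                                "label": loc_to_label.get((name, i, j)),
                            }
                        )
            out["matrices"][name] = entries
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SEMSpec":
        m, p = len(d["latent_names"]), len(d["indicator_names"])
        shapes = {"lam": (p, m), "b": (m, m), "psi": (m, m), "theta": (p, p)}
        mats, frees, labels = {}, {}, {}
        for name, shape in shapes.items():
            mats[name] = np.zeros(shape)
            frees[name] = np.zeros(shape, dtype=bool)
            for e in d["matrices"].get(name, []):
                i, j = e["row"], e["col"]
                mats[name][i, j] = e["value"]
                frees[name][i, j] = e["free"]
                if name in ("psi", "theta"):
                    mats[name][j, i] = e["value"]
                if e.get("label"):
                    labels[e["label"]] = (name, i, j)
        return cls(
            latent_names=list(d["latent_names"]),
            indicator_names=list(d["indicator_names"]),
            lam=mats["lam"],
            lam_free=frees["lam"],
            b=mats["b"],
            b_free=frees["b"],
            psi=mats["psi"],
            psi_free=frees["psi"],
            theta=mats["theta"],
            theta_free=frees["theta"],
            labels=labels,
            focal_label=d.get("focal_label"),
        )

    def start_vector(self) -> np.ndarray:
        """Crude built-in starts (free loadings .7, paths .1, variances .5)."""
        out = []
        for _, mat, i, j in self._params:
            if mat == "lam":
                out.append(0.7)
            elif mat == "b":
                out.append(0.1)
            elif i == j:
                out.append(0.5)
            else:
                out.append(0.1)
        return np.array(out)


def _study_matrices() -> tuple[np.ndarray, ...]:
    m, p = 4, 12
    lam = np.zeros((p, m))
    lam_free = np.zeros((p, m), dtype=bool)
    for k in range(m):
        lam[3 * k, k] = 1.0  # marker identification
        lam_free[3 * k + 1, k] = lam_free[3 * k + 2, k] = True
    b = np.zeros((m, m))
    b_free = np.zeros((m, m), dtype=bool)
    b_free[2, 0] = b_free[2, 1] = True          # eta1 ~ xi1 + xi2
    b_free[3, 0] = b_free[3, 1] = b_free[3, 2] = True  # eta2 ~ xi1 + xi2 + eta1
    psi = np.zeros((m, m))
    psi_free = np.zeros((m, m), dtype=bool)
    psi_free[0, 0] = psi_free[1, 1] = psi_free[1, 0] = True  # exogenous block
    psi_free[2, 2] = psi_free[3, 3] = True                   # structural residuals
    theta = np.zeros((p, p))
    theta_free = np.eye(p, dtype=bool)
    return lam, lam_free, b, b_free, psi, psi_free, theta, theta_free


def linear_sem_spec(focal_label: str = "gamma11") -> SEMSpec:
    """Analysis model for the four-factor linear SEM.

    Latents (xi1, xi2, eta1, eta2), three indicators each (x1..x6, y1..y6),
    marker loadings fixed to 1.  Structural paths carry the conventional
    labels gamma11 (eta1~xi1, the usual focal parameter), gamma12, beta21,
    gamma21, gamma22; phi12 is the exogenous covariance.
    """
    lam, lam_free, b, b_free, psi, psi_free, theta, theta_free = _study_matrices()
    labels = {
        "gamma11": ("b", 2, 0),
        "gamma12": ("b", 2, 1),
        "gamma21": ("b", 3, 0),
        "gamma22": ("b", 3, 1),
        "beta21": ("b", 3, 2),
        "phi1": ("psi", 0, 0),
        "phi2": ("psi", 1, 1),
        "phi12": ("psi", 1, 0),
        "psi1": ("psi", 2, 2),
        "psi2": ("psi", 3, 3),
    }
    return SEMSpec(
        latent_names=["xi1", "xi2", "eta1", "eta2"],
        indicator_names=["x1", "x2", "x3", "x4", "x5", "x6", "y1", "y2", "y3", "y4", "y5", "y6"],
        lam=lam,
        lam_free=lam_free,
        b=b,
        b_free=b_free,
        psi=psi,
        psi_free=psi_free,
        theta=theta,
        theta_free=theta_free,
        labels=labels,
        focal_label=focal_label,
    )


def implied_moments(spec: SEMSpec, theta_vec: np.ndarray) -> np.ndarray:
    """Model-implied indicator covariance Sigma(theta)."""
    lam, b, psi, th = spec.matrices(np.asarray(theta_vec, dtype=float))
    m = b.shape[0]
    imb = np.eye(m) - b
    try:
        a = np.linalg.inv(imb)
    except np.linalg.LinAlgError as exc:
        raise SEMSpecError("I - B is singular") from exc
    sigma_l = a @ psi @ a.T
    return lam @ sigma_l @ lam.T + th


def _dsigma_pairs(
    spec: SEMSpec, lam: np.ndarray, b: np.ndarray, psi: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray, bool]]:
    """Rank-two representation of each dSigma/dtheta_j.

    Every free parameter's derivative is outer(u, v) + outer(v, u) (flag
    True) or outer(u, u) (flag False), which keeps gradient, score and
    information computations O(p) per parameter.
    """
    m, p = b.shape[0], lam.shape[0]
    a = np.linalg.inv(np.eye(m) - b)
    sigma_l = a @ psi @ a.T
    g = lam @ a                     # p x m: total effect of latent k on indicators
    q = lam @ sigma_l               # p x m: Lambda Sigma_latent
    ey = np.eye(p)
    pairs = []
    for _, mat, i, j in spec._params:
        if mat == "lam":
            pairs.append((ey[i], q[:, j], True))
        elif mat == "b":
            pairs.append((g[:, i], lam @ sigma_l[:, j], True))
        elif mat == "psi":
            if i == j:
                pairs.append((g[:, i], g[:, i], False))
            else:
                pairs.append((g[:, i], g[:, j], True))
        else:  # theta
            if i == j:
                pairs.append((ey[i], ey[i], False))
            else:
                pairs.append((ey[i], ey[j], True))
    return pairs


def _fml_and_grad(
    spec: SEMSpec, theta_vec: np.ndarray, s_mat: np.ndarray, logdet_s: float
) -> tuple[float, np.ndarray]:
    p = s_mat.shape[0]
    lam, b, psi, th = spec.matrices(theta_vec)
    m = b.shape[0]
    try:
        a_inv = np.linalg.inv(np.eye(m) - b)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(spec.n_free)
    sigma = lam @ (a_inv @ psi @ a_inv.T) @ lam.T + th
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(spec.n_free)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    sigma_inv = np.linalg.inv(sigma)
    f = logdet + float((sigma_inv * s_mat).sum()) - logdet_s - p
    w = sigma_inv - sigma_inv @ s_mat @ sigma_inv
    grad = np.empty(spec.n_free)
    for k, (u, v, sym2) in enumerate(_dsigma_pairs(spec, lam, b, psi)):
        wu = w @ u
        grad[k] = 2.0 * float(v @ wu) if sym2 else float(u @ wu)
    return f, grad


def _start_values(spec: SEMSpec, data: pd.DataFrame) -> np.ndarray:
    """Automated starts: loadings from marker-scaled covariances, structural
    paths from OLS on marker proxies, variances from proxy residuals."""
    x = data[spec.indicator_names].to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    s = x.T @ x / len(x)
    m = len(spec.latent_names)
    # marker indicator of each latent: the row with a fixed nonzero loading
    markers = []
    for k in range(m):
        fixed = np.where((~spec.lam_free[:, k]) & (spec.lam[:, k] != 0))[0]
        markers.append(int(fixed[0]) if len(fixed) else int(np.argmax(spec.lam_free[:, k])))
    proxy = x[:, markers]
    proxy_cov = proxy.T @ proxy / len(x)

    theta0 = spec.start_vector()
    for idx, (_, mat, i, j) in enumerate(spec._params):
        if mat == "lam":
            theta0[idx] = s[i, markers[j]] / max(proxy_cov[j, j], 1e-3)
        elif mat == "b":
            preds = np.where(spec.b_free[i, :] | (spec.b[i, :] != 0))[0]
            xx = proxy[:, preds]
            try:
                coef = np.linalg.lstsq(xx, proxy[:, i], rcond=None)[0]
                theta0[idx] = float(coef[list(preds).index(j)])
            except np.linalg.LinAlgError:
                pass
        elif mat == "psi":
            if i == j:
                endo = spec.b_free[i, :].any() or (spec.b[i, :] != 0).any()
                theta0[idx] = 0.4 * proxy_cov[i, i] if endo else 0.7 * proxy_cov[i, i]
            else:
                theta0[idx] = 0.7 * proxy_cov[i, j]
        else:  # theta
            theta0[idx] = 0.4 * s[i, i] if i == j else 0.0
    return theta0


def check_identification(spec: SEMSpec, theta_vec: np.ndarray | None = None) -> None:
    """Local identification: the Jacobian of vech(Sigma) with respect to the
    free parameters must have full column rank."""
    if theta_vec is None:
        theta_vec = spec.start_vector()
    lam, b, psi, _ = spec.matrices(np.asarray(theta_vec, dtype=float))
    p = lam.shape[0]
    rows = np.tril_indices(p)
    jac = np.empty((len(rows[0]), spec.n_free))
    for k, (u, v, sym2) in enumerate(_dsigma_pairs(spec, lam, b, psi)):
        d = np.outer(u, v)
        d = d + d.T if sym2 else np.outer(u, u)
        jac[:, k] = d[rows]
    rank = np.linalg.matrix_rank(jac, tol=1e-10)
    if rank < spec.n_free:
        raise SEMSpecError(
            f"model is not locally identified: Jacobian rank {rank} < "
            f"{spec.n_free} free parameters"
        )


@dataclass
class FitResult:
    """ML estimates with naive and (optionally) sandwich standard errors."""

    estimates: pd.Series
    se_naive: pd.Series
    se_robust: pd.Series | None
    loglik: float
    fmin: float
    converged: bool
    reason: str
    n: int
    vcov_naive: np.ndarray | None = None
    vcov_robust: np.ndarray | None = None

    def se(self, robust: bool = False) -> pd.Series:
        if robust:
            if self.se_robust is None:
                raise ValueError("fit was run without robust=True")
            return self.se_robust
        return self.se_naive


@dataclass(frozen=True)
class ZTestResult:
    label: str
    estimate: float
    se: float
    z_value: float
    p_one_sided: float
    p_two_sided: float
    significant: int
    sided: str
    alpha: float


def _hessian_fml(
    spec: SEMSpec, theta_vec: np.ndarray, s_mat: np.ndarray, logdet_s: float
) -> np.ndarray:
    """Central finite differences of the analytic gradient of F_ML."""
    q = len(theta_vec)
    h = 1e-5 * np.maximum(1.0, np.abs(theta_vec))
    hess = np.empty((q, q))
    for j in range(q):
        tp, tm = theta_vec.copy(), theta_vec.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        _, gp = _fml_and_grad(spec, tp, s_mat, logdet_s)
        _, gm = _fml_and_grad(spec, tm, s_mat, logdet_s)
        hess[:, j] = (gp - gm) / (2 * h[j])
    return (hess + hess.T) / 2.0


def fit_ml(
    data: pd.DataFrame,
    spec: SEMSpec,
    robust: bool = False,
    start: np.ndarray | None = None,
    compute_se: bool = True,
) -> FitResult:
    """Fit a SEMSpec to indicator data by normal-theory maximum likelihood.

    Convergence requires gradient norm < 1e-6, a positive-definite implied
    covariance and admissible (non-negative) variance estimates; failures
    are flagged with a reason code, never silent.  ``robust=True`` adds
    sandwich standard errors from casewise scores.
    """
    x = data[spec.indicator_names].to_numpy(dtype=float)
    n, p = x.shape
    if n <= p:
        return _failed_fit(spec, n, "n <= number of indicators")
    xc = x - x.mean(axis=0)
    s_mat = xc.T @ xc / n
    sign, logdet_s = np.linalg.slogdet(s_mat)
    if sign <= 0:
        return _failed_fit(spec, n, "sample covariance not positive definite")

    theta0 = _start_values(spec, data) if start is None else np.asarray(start, float)

    def objective(t: np.ndarray) -> tuple[float, np.ndarray]:
        return _fml_and_grad(spec, t, s_mat, logdet_s)

    res = optimize.minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-8},
    )
    theta_hat = res.x
    f_val, grad = _fml_and_grad(spec, theta_hat, s_mat, logdet_s)
    # Newton polish with step halving if L-BFGS-B stalled short of the
    # gradient tolerance
    polish_iter = 0
    while np.linalg.norm(grad) > _GRAD_TOL and polish_iter < 30:
        hess = _hessian_fml(spec, theta_hat, s_mat, logdet_s)
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(len(grad)), grad)
        except np.linalg.LinAlgError:
            break
        t, improved = 1.0, False
        for _ in range(25):
            cand = theta_hat - t * step
            f_new, g_new = _fml_and_grad(spec, cand, s_mat, logdet_s)
            if f_new <= f_val or np.linalg.norm(g_new) < np.linalg.norm(grad):
                theta_hat, f_val, grad = cand, f_new, g_new
                improved = True
                break
            t *= 0.5
        if not improved:
            break
        polish_iter += 1

    reason = "ok"
    converged = True
    if np.linalg.norm(grad) > _GRAD_TOL:
        converged, reason = False, "max-iterations (gradient norm above tolerance)"
    sigma_hat = implied_moments(spec, theta_hat)
    if converged and np.linalg.eigvalsh(sigma_hat).min() <= 0:
        converged, reason = False, "implied covariance not positive definite"
    if converged:
        for val, (_, mat, i, j) in zip(theta_hat, spec._params):
            if mat in ("psi", "theta") and i == j and val < 0:
                converged, reason = False, "negative variance estimate (Heywood)"
                break

    loglik = -0.5 * n * (p * math.log(2 * math.pi) + logdet_s + p + f_val)
    labels = spec.param_labels
    estimates = pd.Series(theta_hat, index=labels)
    se_naive = pd.Series(np.nan, index=labels)
    se_robust = None
    vcov_naive = vcov_robust = None

    if converged and compute_se:
        hess = _hessian_fml(spec, theta_hat, s_mat, logdet_s)
        info = 0.5 * n * hess  # observed information of the total log-likelihood
        try:
            vcov_naive = np.linalg.inv(info)
            diag = np.diag(vcov_naive)
            if np.any(diag <= 0):
                converged, reason = False, "information matrix not positive definite"
            else:
                se_naive = pd.Series(np.sqrt(diag), index=labels)
        except np.linalg.LinAlgError:
            converged, reason = False, "information matrix singular"
        if converged and robust:
            scores = _casewise_scores(spec, theta_hat, xc, sigma_hat)
            meat = scores.T @ scores
            vcov_robust = vcov_naive @ meat @ vcov_naive
            se_robust = pd.Series(np.sqrt(np.diag(vcov_robust)), index=labels)

    return FitResult(
        estimates=estimates,
        se_naive=se_naive,
        se_robust=se_robust,
        loglik=loglik,
        fmin=f_val,
        converged=converged,
        reason=reason,
        n=n,
        vcov_naive=vcov_naive,
        vcov_robust=vcov_robust,
    )


def _failed_fit(spec: SEMSpec, n: int, reason: str) -> FitResult:
    labels = spec.param_labels
    nan = pd.Series(np.nan, index=labels)
    return FitResult(
        estimates=nan.copy(),
        se_naive=nan.copy(),
        se_robust=None,
        loglik=np.nan,
        fmin=np.nan,
        converged=False,
        reason=reason,
        n=n,
    )


def _casewise_scores(
    spec: SEMSpec, theta_vec: np.ndarray, xc: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """Per-observation score vectors of the normal log-likelihood.

    d l_i / d theta_j = -1/2 [tr(Sigma^-1 dSigma_j)
                              - x_i' Sigma^-1 dSigma_j Sigma^-1 x_i].
    """
    lam, b, psi, _ = spec.matrices(theta_vec)
    prec = np.linalg.inv(sigma)
    xp = xc @ prec
    scores = np.empty((len(xc), spec.n_free))
    for k, (u, v, sym2) in enumerate(_dsigma_pairs(spec, lam, b, psi)):
        pu = prec @ u
        au = xp @ u
        if sym2:
            tr = 2.0 * float(v @ pu)
            quad = 2.0 * au * (xp @ v)
        else:
            tr = float(u @ pu)
            quad = au * au
        scores[:, k] = -0.5 * (tr - quad)
    return scores


def z_test(
    fit: FitResult,
    label: str | None = None,
    sided: Literal["one-sided", "two-sided"] = "two-sided",
    alpha: float = 0.05,
    robust: bool = False,
    hypothesized_sign: int = 1,
) -> ZTestResult:
    """z-test of a single parameter: z = estimate / SE.

    One-sided tests multiply z by the hypothesized sign of the population
    effect before comparing with q_{1-alpha}; two-sided tests compare |z|
    with q_{1-alpha/2}.
    """
    if not fit.converged:
        raise ValueError(f"cannot test a non-converged fit ({fit.reason})")
    if label is None:
        raise KeyError("a parameter label is required")
    if label not in fit.estimates.index:
        raise KeyError(f"unknown parameter label {label!r}")
    est = float(fit.estimates[label])
    se = float(fit.se(robust)[label])
    z = est / se
    p_one = float(special.ndtr(-hypothesized_sign * z))
    p_two = float(2 * special.ndtr(-abs(z)))
    if sided == "one-sided":
        sig = int(hypothesized_sign * z > stats.norm.ppf(1 - alpha))
    else:
        sig = int(abs(z) > stats.norm.ppf(1 - alpha / 2))
    return ZTestResult(
        label=label,
        estimate=est,
        se=se,
        z_value=z,
        p_one_sided=p_one,
        p_two_sided=p_two,
        significant=sig,
        sided=sided,
        alpha=alpha,
    )


def make_product_indicators(
    data: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Append matched, double-mean-centered product indicator columns.

    Each raw indicator in a pair is mean-centered, the products formed, and
    the product columns centered again, so every product column has exactly
    zero sample mean.  An indicator may appear in at most one pair
    (matched products).
    """
    used: set[str] = set()
    for a, b in pairs:
        if a == b:
            raise SEMSpecError(f"pair ({a}, {b}) must reference distinct columns")
        for col in (a, b):
            if col not in data.columns:
                raise SEMSpecError(f"column {col!r} not in data")
            if col in used:
                raise SEMSpecError(
                    f"indicator {col!r} is used in more than one product pair"
                )
            used.add(col)
    out = data.copy()
    for a, b in pairs:
        prod = (data[a] - data[a].mean()) * (data[b] - data[b].mean())
        out[f"{a}.{b}"] = prod - prod.mean()
    return out


def build_upi_spec(
    base: SEMSpec,
    pairs: Sequence[tuple[str, str]],
    interacting: tuple[str, str] = ("xi1", "xi2"),
    target: str = "eta1",
    focal_label: str = "gamma13",
) -> SEMSpec:
    """Augment a linear SEM with an unconstrained product-indicator
    interaction factor.

    The interaction latent is measured by the product indicators (marker
    loading fixed to 1, others free), covaries freely with all exogenous
    latents, has a free variance and free product-indicator residual
    variances, and enters the target endogenous latent through one new free
    structural path (the focal interaction effect).  No nonlinear
    constraints are imposed (the "unconstrained" variant).
    """
    if len(pairs) == 0:
        return base
    for name in interacting + (target,):
        if name not in base.latent_names:
            raise SEMSpecError(f"latent {name!r} not in the base model")
    m, p = len(base.latent_names), len(base.indicator_names)
    # insert the interaction latent after the exogenous block
    exo = [
        k
        for k in range(m)
        if not (base.b_free[k, :].any() or (base.b[k, :] != 0).any())
    ]
    pos = max(exo) + 1
    prod_names = [f"{a}.{b}" for a, b in pairs]
    new_latents = base.latent_names[:pos] + [f"{interacting[0]}{interacting[1]}"] + base.latent_names[pos:]
    new_indicators = list(base.indicator_names) + prod_names
    q = len(pairs)

    def grow(mat: np.ndarray, rows: int, cols: int, at_row: int, at_col: int) -> np.ndarray:
        out = np.insert(mat, [at_row] * rows, 0, axis=0) if rows else mat
        return np.insert(out, [at_col] * cols, 0, axis=1) if cols else out

    lam = grow(base.lam.astype(float), 0, 1, 0, pos)
    lam = np.vstack([lam, np.zeros((q, m + 1))])
    lam_free = grow(base.lam_free, 0, 1, 0, pos).astype(bool)
    lam_free = np.vstack([lam_free, np.zeros((q, m + 1), dtype=bool)])
    lam[p, pos] = 1.0  # marker product indicator
    for r in range(1, q):
        lam_free[p + r, pos] = True

    b = grow(base.b.astype(float), 1, 1, pos, pos)
    b_free = grow(base.b_free, 1, 1, pos, pos).astype(bool)
    t_idx = new_latents.index(target)
    b_free[t_idx, pos] = True

    psi = grow(base.psi.astype(float), 1, 1, pos, pos)
    psi_free = grow(base.psi_free, 1, 1, pos, pos).astype(bool)
    psi_free[pos, pos] = True
    for k in exo:
        kk = k if k < pos else k + 1
        psi_free[max(pos, kk), min(pos, kk)] = True

    theta = np.zeros((p + q, p + q))
    theta[:p, :p] = base.theta
    theta_free = np.zeros((p + q, p + q), dtype=bool)
    theta_free[:p, :p] = base.theta_free
    for r in range(q):
        theta_free[p + r, p + r] = True

    def shift(loc: tuple[str, int, int]) -> tuple[str, int, int]:
        mat, i, j = loc
        if mat == "lam":
            return (mat, i, j + 1 if j >= pos else j)
        if mat in ("b", "psi"):
            i2 = i + 1 if i >= pos else i
            j2 = j + 1 if j >= pos else j
            return (mat, max(i2, j2), min(i2, j2)) if mat == "psi" else (mat, i2, j2)
        return loc

    labels = {name: shift(loc) for name, loc in base.labels.items()}
    labels[focal_label] = ("b", t_idx, pos)
    return SEMSpec(
        latent_names=new_latents,
        indicator_names=new_indicators,
        lam=lam,
        lam_free=lam_free,
        b=b,
        b_free=b_free,
        psi=psi,
        psi_free=psi_free,
        theta=theta,
        theta_free=theta_free,
        labels=labels,
        focal_label=focal_label,
    )
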