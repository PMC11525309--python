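"""Orchestration of simulation-based power studies.

A power study allocates sample sizes across R replications, simulates a
dataset at each, fits the analysis model, applies the z-test to the focal
parameter, and logs the binary significance decision.  The resulting
decision log is then fed to the power-curve models, which are inverted for
required sample sizes.  The module also computes empirical reference power
(relative frequency of significance among converged replications with an
exact binomial interval) and the evaluation metrics used to compare
power-modeling methods: bias and RMSE of the estimated required sample
size, bias of the predicted power at the reference N, and the frequency of
the lower-bound sample size undershooting the true requirement (a proxy
for the type I error of the lower-bound rule, expected near alpha_rho/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from . import power_model as pm
from . import sem_engine, synthetic_data
from .errors import ConfigurationError, MSPEError
from .power_model import PowerModelFit, SampleSizeResult, SignificanceRecord

__all__ = [
    "UniformAllocation",
    "FourPointAllocation",
    "StudyConfig",
    "StudyResult",
    "EvaluationResult",
    "allocate_sample_sizes",
    "simulate_bernoulli_decisions",
    "run_power_study",
    "estimate_reference_power",
    "evaluate_methods",
    "reference_grid",
]


class StudyAbortedError(MSPEError):
    """More than half of the replications failed to converge."""


@dataclass(frozen=True)
class UniformAllocation:
    """Cycle every integer sample size in [n_min, n_max]."""

    n_min: int
    n_max: int

    def __post_init__(self) -> None:
        if self.n_max <= self.n_min:
            raise ConfigurationError("uniform allocation range is degenerate")


@dataclass(frozen=True)
class FourPointAllocation:
    """Four ad hoc sample sizes for the naive interpolation baseline."""

    n1: int
    n2: int
    n3: int
    n4: int

    @property
    def grid(self) -> tuple[int, int, int, int]:
        return (self.n1, self.n2, self.n3, self.n4)

    def __post_init__(self) -> None:
        if len(set(self.grid)) != 4 or list(self.grid) != sorted(self.grid):
            raise ConfigurationError(
                "four-point allocation requires 4 strictly increasing sample sizes"
            )


def allocate_sample_sizes(
    R: int, allocation: UniformAllocation | FourPointAllocation
) -> np.ndarray:
    """Expand an allocation scheme into the per-replication sample sizes.

    Uniform: the integer grid n_min..n_max is cycled until R values are
    emitted, so R = k * gridsize gives each size exactly k times.
    Four-point: R is split as evenly as possible across the four sizes with
    any remainder assigned to the smallest.
    """
    if isinstance(allocation, UniformAllocation):
        grid = np.arange(allocation.n_min, allocation.n_max + 1)
        if R < len(grid) and R < 2:
            raise ConfigurationError("R too small for the allocation grid")
        reps = int(np.ceil(R / len(grid)))
        return np.tile(grid, reps)[:R]
    base, rem = divmod(R, 4)
    counts = [base + rem, base, base, base]
    return np.repeat(np.array(allocation.grid), counts)


def simulate_bernoulli_decisions(
    beta0: float,
    beta1: float,
    n_values: Sequence[int],
    rng: np.random.Generator,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Idealized decision log: Bernoulli draws straight from a known power
    curve (probit on sqrt(n), or the two-term two-sided variant).

    Used as the ground-truth generator in calibration experiments, where
    the fitted power model can be compared with the curve that actually
    produced the decisions.
    """
    n_arr = np.asarray(n_values, dtype=float)
    if two_sided:
        p = special.ndtr(beta0 + beta1 * np.sqrt(n_arr)) + special.ndtr(
            beta0 - beta1 * np.sqrt(n_arr)
        )
    else:
        p = special.ndtr(beta0 + beta1 * np.sqrt(n_arr))
    s = (rng.random(len(n_arr)) < p).astype(int)
    return pd.DataFrame(
        {
            "n": n_arr.astype(int),
            "significant": s,
            "converged": 1,
            "replicate_id": np.arange(len(n_arr)),
        }
    )


@dataclass
class StudyConfig:
    """Everything needed to run one power study end to end."""

    generation: synthetic_data.GenerationConfig
    spec: sem_engine.SEMSpec | None = None
    upi_pairs: tuple[tuple[str, str], ...] | None = None
    focal_label: str = "gamma11"
    test: Literal["one-sided", "two-sided"] = "two-sided"
    alpha: float = 0.05
    rho: float = 0.80
    alpha_rho: float = 0.05
    R: int = 550
    allocation: UniformAllocation | FourPointAllocation = field(
        default_factory=lambda: UniformAllocation(51, 600)
    )
    master_seed: int = 0
    methods: tuple[str, ...] = ("probit_sqrt",)
    robust: bool = False
    hypothesized_sign: int = 1

    def __post_init__(self) -> None:
        if self.R < 8:
            raise ConfigurationError("R must be at least 8")
        if self.rho > pm.POWER_CAP:
            raise ConfigurationError(f"rho must be <= {pm.POWER_CAP}")

    def resolved_spec(self) -> sem_engine.SEMSpec:
        spec = self.spec if self.spec is not None else sem_engine.linear_sem_spec()
        if self.upi_pairs:
            spec = sem_engine.build_upi_spec(spec, self.upi_pairs)
        return spec


@dataclass
class StudyResult:
    records: pd.DataFrame
    fits: dict[str, PowerModelFit]
    sample_sizes: dict[str, SampleSizeResult]
    errors: dict[str, str]
    nonconvergence_rate: float


def _default_decision(
    config: StudyConfig, spec: sem_engine.SEMSpec, n: int, seed
) -> tuple[int, int]:
    """Simulate one dataset, fit the SEM, and run the focal z-test."""
    data = synthetic_data.generate_dataset(config.generation, n=n, seed=seed)
    if config.upi_pairs:
        data = sem_engine.make_product_indicators(data, config.upi_pairs)
    fit = sem_engine.fit_ml(data, spec, robust=config.robust)
    if not fit.converged:
        return 0, 0
    zt = sem_engine.z_test(
        fit,
        config.focal_label,
        sided=config.test,
        alpha=config.alpha,
        robust=config.robust,
        hypothesized_sign=config.hypothesized_sign,
    )
    return zt.significant, 1


def run_power_study(
    config: StudyConfig,
    decision_fn: Callable[[pd.DataFrame, StudyConfig], tuple[int, int]] | None = None,
) -> StudyResult:
    """Run a full power study: simulate, test, log, fit, invert.

    ``decision_fn(dataset, config) -> (significant, converged)`` lets an
    external estimator supply the significance decisions; by default the
    built-in ML fitter and z-test are used.  Replication i draws its data
    from the i-th spawned substream of the master seed, so serial and
    parallel execution produce identical logs.  Aborts if more than half
    the replications fail to converge (a power fit on the remainder would
    be unreliable).
    """
    n_values = allocate_sample_sizes(config.R, config.allocation)
    spec = config.resolved_spec()
    streams = np.random.SeedSequence(config.master_seed).spawn(len(n_values))
    rows = []
    for i, (n, ss) in enumerate(zip(n_values, streams)):
        if decision_fn is None:
            sig, conv = _default_decision(config, spec, int(n), ss)
        else:
            data = synthetic_data.generate_dataset(config.generation, n=int(n), seed=ss)
            sig, conv = decision_fn(data, config)
        rows.append(
            {"n": int(n), "significant": sig, "converged": conv, "replicate_id": i}
        )
    records = pd.DataFrame(rows)
    nonconv = 1.0 - records["converged"].mean()
    if nonconv > 0.5:
        raise StudyAbortedError(
            f"{nonconv:.0%} of replications failed to converge; the power fit "
            "would be unreliable. Check the model or increase sample sizes."
        )
    fits: dict[str, PowerModelFit] = {}
    sizes: dict[str, SampleSizeResult] = {}
    errors: dict[str, str] = {}
    for method in config.methods:
        try:
            if method == "naive":
                fit = pm.fit_naive(records, alpha_rho=config.alpha_rho)
            else:
                fit = pm.fit_power_model(records, method=method, alpha=config.alpha)
            fits[method] = fit
            sizes[method] = pm.required_n_lb(
                fit, config.rho, alpha_rho=config.alpha_rho
            )
        except MSPEError as exc:
            errors[method] = f"{type(exc).__name__}: {exc}"
    return StudyResult(
        records=records,
        fits=fits,
        sample_sizes=sizes,
        errors=errors,
        nonconvergence_rate=nonconv,
    )


def estimate_reference_power(
    config: StudyConfig,
    n: int,
    R_ref: int,
    seed: int | None = None,
    decision_fn: Callable[[pd.DataFrame, StudyConfig], tuple[int, int]] | None = None,
) -> tuple[float, tuple[float, float]]:
    """Empirical power at a fixed n: relative frequency of significance
    among converged replications, with an exact (Clopper-Pearson) interval
    at level 1 - alpha_rho."""
    if R_ref < 100:
        raise ConfigurationError("R_ref must be at least 100")
    master = config.master_seed if seed is None else seed
    streams = np.random.SeedSequence(master).spawn(R_ref)
    spec = config.resolved_spec()
    sigs, convs = 0, 0
    for ss in streams:
        if decision_fn is None:
            sig, conv = _default_decision(config, spec, int(n), ss)
        else:
            data = synthetic_data.generate_dataset(config.generation, n=int(n), seed=ss)
            sig, conv = decision_fn(data, config)
        sigs += sig * conv
        convs += conv
    if convs == 0:
        raise StudyAbortedError("no replication converged at this sample size")
    p_hat = sigs / convs
    a = config.alpha_rho
    lo = stats.beta.ppf(a / 2, sigs, convs - sigs + 1) if sigs > 0 else 0.0
    hi = stats.beta.ppf(1 - a / 2, sigs + 1, convs - sigs) if sigs < convs else 1.0
    return p_hat, (float(lo), float(hi))


def reference_grid(model: Literal["linear_sem", "qisem"]) -> np.ndarray:
    """Reference sample sizes at which empirical power is evaluated:
    50, 70, ..., 650 for the linear SEM (31 points) and 150, 200, ..., 1200
    for the QISEM (22 points)."""
    if model == "linear_sem":
        return np.arange(50, 651, 20)
    if model == "qisem":
        return np.arange(150, 1201, 50)
    raise ConfigurationError(f"unknown model {model!r}")


@dataclass(frozen=True)
class EvaluationResult:
    """Method-evaluation metrics across repeated studies at one reference n."""

    bias_N: float
    bias_rho: float | None
    rmse_N: float
    typeI: float
    reps_c: int


def evaluate_methods(
    results: pd.DataFrame,
    n_alpha_true: int,
    rho_ref: float | None = None,
) -> EvaluationResult:
    """Aggregate per-study inversion results against the reference truth.

    ``results`` needs columns ``N_alpha`` and ``N_lb`` (one row per
    converged study repetition) and optionally ``rho_at_ref``, the study's
    predicted power at the true required sample size, compared against the
    reference power ``rho_ref``.
    """
    for col in ("N_alpha", "N_lb"):
        if col not in results.columns:
            raise ConfigurationError(f"results must contain a {col!r} column")
    reps = len(results)
    if reps < 1:
        raise ConfigurationError("need at least one converged study repetition")
    dev = results["N_alpha"].to_numpy(dtype=float) - n_alpha_true
    bias_rho = None
    if rho_ref is not None and "rho_at_ref" in results.columns:
        bias_rho = float(results["rho_at_ref"].mean() - rho_ref)
    return EvaluationResult(
        bias_N=float(dev.mean()),
        bias_rho=bias_rho,
        rmse_N=float(np.sqrt((dev**2).mean())),
        typeI=float((results["N_lb"].to_numpy() < n_alpha_true).mean()),
        reps_c=reps,
    )
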