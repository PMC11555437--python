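"""Variance-component score tests with permutation min-P calibration.

For one input kernel the analysis is:

1. fit the null model y = a10 + T a20 + Z a30 (+ error) by OLS (gaussian)
   or maximum-likelihood logistic regression (binomial), keeping the
   response residuals r = y - yhat0;
2. build three endogenous gram matrices from the surrogate variants X*:
   K_M = X* X*' (main effects), K_I = (X* . T)(X* . T)' (treatment
   interactions, row-wise Hadamard product with T), and K_B = K_M + K_I
   (both);
3. score statistics T = r' K r for each, with permutation nulls obtained by
   rearranging r — one shared permutation plan for every statistic;
4. empirical p-values P = (1/R) sum I(T(r) >= T_obs), and the per-kernel
   min-P statistic T_h = min(P_M, P_I, P_B) recalibrated against its own
   permutation null via a leave-one-out rank transform.

The statistics estimate the squared-effect sums b1'b1, b2'b2 and their sum
without ever fitting b1, b2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .ecological_kernels import Kernel
from .formats_io import SampleMetadata
from .surrogate_pca import SurrogateVariants, extract_surrogates

__all__ = [
    "NullModelFit",
    "PermutationPlan",
    "EndogenousKernels",
    "SingleKernelResult",
    "fit_null",
    "build_endogenous",
    "score_stat",
    "empirical_pvalue",
    "leave_one_out_pvalues",
    "minp_single_kernel",
    "single_kernel_test",
    "multi_kernel_test",
]

TARGETS = ("M", "I", "B")


@dataclass
class NullModelFit:
    """Null model fit (no variant effects): coefficients, fitted values and
    response residuals y - yhat0."""

    family: str
    coefficients: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    design: np.ndarray


def fit_null(meta: SampleMetadata) -> NullModelFit:
    """Fit the null model on the design (1, T, Z).

    Gaussian responses use OLS; binomial responses use maximum-likelihood
    logistic regression. Residuals are response residuals y - yhat0 for both
    families.
    """
    n = meta.n_samples
    X = np.column_stack([np.ones(n), meta.T, meta.Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient null design matrix")
    if meta.family == "gaussian":
        coef, *_ = np.linalg.lstsq(X, meta.y, rcond=None)
        fitted = X @ coef
    else:
        if np.all(meta.y == meta.y[0]):
            raise ValueError("degenerate response: all values equal")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.GLM(meta.y, X, family=sm.families.Binomial()).fit()
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise ValueError("perfect separation in binomial null model") from exc
        coef = np.asarray(res.params)
        fitted = np.asarray(res.fittedvalues)
    return NullModelFit(meta.family, coef, fitted, meta.y - fitted, X)


@dataclass
class PermutationPlan:
    """R rearrangements of 1..n, shared by every statistic of one analysis."""

    permutations: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.permutations = np.asarray(self.permutations)
        if self.permutations.ndim != 2:
            raise ValueError("permutations must be an R x n array")
        n = self.permutations.shape[1]
        expected = np.arange(n)
        if not np.all(np.sort(self.permutations, axis=1) == expected):
            raise ValueError("each row must be a permutation of 0..n-1")

    @property
    def R(self) -> int:
        return self.permutations.shape[0]

    @property
    def n(self) -> int:
        return self.permutations.shape[1]

    @classmethod
    def generate(cls, n: int, R: int, seed: int | np.random.Generator) -> "PermutationPlan":
        rng = np.random.default_rng(seed)
        perms = np.argsort(rng.random((R, n)), axis=1)
        return cls(perms, seed=seed if isinstance(seed, (int, np.integer)) else None)


@dataclass
class EndogenousKernels:
    """The three endogenous gram matrices for one input kernel."""

    kM: np.ndarray
    kI: np.ndarray
    kB: np.ndarray
    measure: str = ""


def build_endogenous(surrogates: SurrogateVariants, T: np.ndarray) -> EndogenousKernels:
    """K_M = X* X*', K_I = (X* . T)(X* . T)', K_B = K_M + K_I.

    K_B equals the gram matrix of the concatenation (X* | X* . T) exactly.
    """
    T = np.asarray(T, dtype=float).ravel()
    Xm = surrogates.matrix
    if Xm.shape[0] != T.shape[0]:
        raise ValueError("treatment vector length does not match surrogates")
    Xi = Xm * T[:, None]
    kM = Xm @ Xm.T
    kI = Xi @ Xi.T
    return EndogenousKernels(kM, kI, kM + kI, surrogates.measure)


def score_stat(residuals: np.ndarray, K: np.ndarray) -> float:
    """Variance-component score statistic: the quadratic form r' K r."""
    r = np.asarray(residuals, dtype=float).ravel()
    K = np.asarray(K, dtype=float)
    if K.shape != (r.shape[0], r.shape[0]):
        raise ValueError("dimension mismatch between residuals and kernel")
    return float(r @ K @ r)


def quantize_stats(observed: float, null: np.ndarray) -> tuple[float, np.ndarray]:
    """Snap statistics to a relative grid of ~1e-12 before rank comparisons.

    The p-value definitions count ties (>= / <=), and rearrangements that are
    mathematically tied (e.g. the identity rearrangement vs the observed
    statistic, or permutations within a constant treatment group) must count
    as ties regardless of floating-point summation order. The grid scale is
    snapped to a power of two so the convention is implementation-independent.
    """
    null = np.asarray(null, dtype=float)
    s = max(float(np.max(np.abs(null), initial=0.0)), abs(observed))
    if s == 0.0:
        return observed, null
    grid = 2.0 ** np.ceil(np.log2(s)) * 1e-12
    return float(np.round(observed / grid) * grid), np.round(null / grid) * grid


def empirical_pvalue(observed: float, null: np.ndarray) -> float:
    """P = (1/R) sum_r I(T(r) >= T_obs); the observed value is not added to
    the null set, so the smallest attainable p-value is 0 at resolution 1/R."""
    null = np.asarray(null)
    return float(np.mean(null >= observed))


def leave_one_out_pvalues(null: np.ndarray) -> np.ndarray:
    """For each r', the p-value of T(r') against the other R-1 null values:
    (1/(R-1)) sum_{r != r'} I(T(r) >= T(r'))."""
    null = np.asarray(null, dtype=float)
    R = null.shape[0]
    if R < 2:
        raise ValueError("need at least 2 permutations")
    srt = np.sort(null)
    n_less = np.searchsorted(srt, null, side="left")
    count_ge = R - n_less  # includes self
    return (count_ge - 1) / (R - 1)


def minp_single_kernel(
    pvalues: dict[str, float], loo: dict[str, np.ndarray]
) -> tuple[float, np.ndarray, float]:
    """Min-P across the three endogenous tests, recalibrated by permutation.

    T_h = min(P_M, P_I, P_B); its null values are the per-rearrangement
    minima of the leave-one-out p-values, and P_h is the proportion of null
    minima <= T_h.
    """
    t_obs = min(pvalues[t] for t in TARGETS)
    null_min = np.minimum.reduce([np.asarray(loo[t]) for t in TARGETS])
    p = float(np.mean(null_min <= t_obs))
    return t_obs, null_min, p


@dataclass
class SingleKernelResult:
    """All statistics and p-values of one input kernel's analysis."""

    measure: str
    observed: dict[str, float]
    null_stats: dict[str, np.ndarray]
    pvalues: dict[str, float]
    loo_pvalues: dict[str, np.ndarray]
    t_minp: float
    minp_null: np.ndarray
    p_minp: float
    df: int = 0

    @property
    def R(self) -> int:
        return next(iter(self.null_stats.values())).shape[0]

    def summary(self) -> dict[str, float]:
        return {
            "P_M": self.pvalues["M"],
            "P_I": self.pvalues["I"],
            "P_B": self.pvalues["B"],
            "P_minp": self.p_minp,
        }


def _permuted_stats(
    residuals: np.ndarray, plan: PermutationPlan, Xm: np.ndarray, Xi: np.ndarray
) -> dict[str, np.ndarray]:
    """Null score statistics for all rearrangements via stacked matrix
    products: T(r) = || X' P_r r ||^2 for each factor X."""
    Rm = residuals[plan.permutations]  # (R, n)
    Bm = Rm @ Xm
    Bi = Rm @ Xi
    TM = np.einsum("ij,ij->i", Bm, Bm)
    TI = np.einsum("ij,ij->i", Bi, Bi)
    return {"M": TM, "I": TI, "B": TM + TI}


def single_kernel_test(
    kernel: Kernel | np.ndarray,
    null_fit: NullModelFit,
    T: np.ndarray,
    plan: PermutationPlan,
    df: int | str = "full",
) -> SingleKernelResult:
    """Run the three endogenous score tests plus min-P for one input kernel."""
    surrogates = extract_surrogates(kernel, df=df)
    return _test_from_surrogates(surrogates, null_fit, np.asarray(T, float).ravel(), plan)


def _test_from_surrogates(
    surrogates: SurrogateVariants,
    null_fit: NullModelFit,
    T: np.ndarray,
    plan: PermutationPlan,
) -> SingleKernelResult:
    r = null_fit.residuals
    if surrogates.matrix.shape[0] != r.shape[0] or plan.n != r.shape[0]:
        raise ValueError("sample-size mismatch between surrogates, residuals and plan")
    Xm = surrogates.matrix
    Xi = Xm * T[:, None]
    obs_M = float(np.sum((Xm.T @ r) ** 2))
    obs_I = float(np.sum((Xi.T @ r) ** 2))
    observed = {"M": obs_M, "I": obs_I, "B": obs_M + obs_I}
    null_stats = _permuted_stats(r, plan, Xm, Xi)
    for t in TARGETS:
        observed[t], null_stats[t] = quantize_stats(observed[t], null_stats[t])
    pvalues = {t: empirical_pvalue(observed[t], null_stats[t]) for t in TARGETS}
    loo = {t: leave_one_out_pvalues(null_stats[t]) for t in TARGETS}
    t_minp, minp_null, p_minp = minp_single_kernel(pvalues, loo)
    return SingleKernelResult(
        measure=surrogates.measure,
        observed=observed,
        null_stats=null_stats,
        pvalues=pvalues,
        loo_pvalues=loo,
        t_minp=t_minp,
        minp_null=minp_null,
        p_minp=p_minp,
        df=surrogates.df,
    )


def multi_kernel_test(
    kernels: dict[str, Kernel | np.ndarray],
    null_fit: NullModelFit,
    T: np.ndarray,
    plan: PermutationPlan,
    df: int | str = "full",
) -> dict[str, SingleKernelResult]:
    """Run the per-kernel analysis for every input kernel under one shared
    permutation plan (required for the omnibus null to capture dependence)."""
    T = np.asarray(T, dtype=float).ravel()
    return {
        label: single_kernel_test(kernel, null_fit, T, plan, df=df)
        for label, kernel in kernels.items()
    }
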