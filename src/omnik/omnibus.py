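"""Min-P omnibus testing across multiple input kernels (OmniK), plus
Fisher / Brown / Simes combiners for comparison.

OmniK is a two-level min-P recalibration. Level one, per effect target
e in {M, I, B}: the observed statistic is the minimum over input kernels of
the per-kernel p-values, min_h P^e_(h); its permutation null is the same
minimum formed from the leave-one-out p-values of each rearrangement, and
the omnibus p-value P^e_OmniK is the proportion of null minima at or below
the observed one. Level two: T_OmniK = min(P^M_OmniK, P^I_OmniK, P^B_OmniK)
is recalibrated the same way against the leave-one-out ranks of the level-one
null minima. Because every quantity reuses the single shared permutation
plan, the null distributions capture the dependence among the combined
p-values — which is exactly what naive Fisher/Simes combination ignores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kernel_association_test import TARGETS, SingleKernelResult

__all__ = [
    "OmniKResult",
    "AltCombineResult",
    "omnik_endogenous",
    "omnik_overall",
    "omnik",
    "combine_alt",
]


@dataclass
class OmniKResult:
    """Observed statistics and p-values of the two-level omnibus test."""

    t_omnik_endog: dict[str, float]  # min_h P^e_(h), e in M/I/B
    p_omnik_endog: dict[str, float]  # their recalibrated p-values
    t_omnik: float  # min of the three p_omnik_endog
    p_omnik: float
    measures: tuple[str, ...] = ()
    R: int = 0

    def summary(self) -> dict[str, float]:
        return {
            "P_M": self.p_omnik_endog["M"],
            "P_I": self.p_omnik_endog["I"],
            "P_B": self.p_omnik_endog["B"],
            "P_OmniK": self.p_omnik,
        }


def _check_shared_plan(results: dict[str, SingleKernelResult]) -> int:
    Rs = {res.R for res in results.values()}
    if len(Rs) != 1:
        raise ValueError("all per-kernel results must share one permutation plan")
    return Rs.pop()


def _loo_rank_small(values: np.ndarray) -> np.ndarray:
    """Leave-one-out rank transform for a small-is-extreme statistic:
    (1/(R-1)) sum_{r != r'} I(v(r) <= v(r'))."""
    values = np.asarray(values, dtype=float)
    R = values.shape[0]
    srt = np.sort(values)
    count_le = np.searchsorted(srt, values, side="right")  # includes self
    return (count_le - 1) / (R - 1)


def omnik_endogenous(
    results: dict[str, SingleKernelResult],
) -> tuple[dict[str, float], dict[str, np.ndarray], dict[str, float]]:
    """Level one: per effect target, min over kernels of the p-values,
    its null min array, and the recalibrated omnibus p-value."""
    _check_shared_plan(results)
    t_obs: dict[str, float] = {}
    null_min: dict[str, np.ndarray] = {}
    p_omni: dict[str, float] = {}
    for target in TARGETS:
        t_obs[target] = min(res.pvalues[target] for res in results.values())
        null_min[target] = np.minimum.reduce(
            [res.loo_pvalues[target] for res in results.values()]
        )
        p_omni[target] = float(np.mean(null_min[target] <= t_obs[target]))
    return t_obs, null_min, p_omni


def omnik_overall(
    p_omni: dict[str, float], null_min: dict[str, np.ndarray]
) -> tuple[float, float]:
    """Level two: recalibrate min(P^M, P^I, P^B)_OmniK against the
    leave-one-out ranks of the level-one null minima (no new permutations)."""
    t_omnik = min(p_omni[t] for t in TARGETS)
    null_t = np.minimum.reduce([_loo_rank_small(null_min[t]) for t in TARGETS])
    p_omnik = float(np.mean(null_t <= t_omnik))
    return t_omnik, p_omnik


def omnik(results: dict[str, SingleKernelResult]) -> OmniKResult:
    """Full OmniK omnibus over per-kernel results sharing one plan."""
    R = _check_shared_plan(results)
    t_obs, null_min, p_omni = omnik_endogenous(results)
    t_omnik, p_omnik = omnik_overall(p_omni, null_min)
    return OmniKResult(
        t_omnik_endog=t_obs,
        p_omnik_endog=p_omni,
        t_omnik=t_omnik,
        p_omnik=p_omnik,
        measures=tuple(results),
        R=R,
    )


@dataclass
class AltCombineResult:
    method: str
    pvalue: float
    statistic: float
    input_pvalues: np.ndarray


def combine_alt(
    pvalues,
    method: str,
    null_p_matrix: np.ndarray | None = None,
    zero_replacement: float | None = None,
) -> AltCombineResult:
    """Combine dependent p-values by Fisher, Brown or Simes.

    Fisher: X2 = -2 sum ln p against chi-square(2m) — assumes independence.
    Simes: min_k m p_(k) / k. Brown: Fisher's statistic against a scaled
    chi-square whose scale and df are moment-matched using the covariance of
    -2 ln p estimated from ``null_p_matrix`` (rows = rearrangements, columns
    aligned with ``pvalues``). Zero p-values (below permutation resolution)
    are replaced by ``zero_replacement`` (default 1/R when a null matrix is
    given) with a warning.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    m = p.shape[0]
    if m < 2:
        raise ValueError("need at least 2 p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        if zero_replacement is None:
            if null_p_matrix is None:
                raise ValueError(
                    "p = 0 at permutation resolution: pass zero_replacement (e.g. 1/R)"
                )
            zero_replacement = 1.0 / null_p_matrix.shape[0]
        warnings.warn(
            f"p-value of 0 replaced by {zero_replacement:g} (permutation resolution)",
            stacklevel=2,
        )
        p = np.where(p == 0, zero_replacement, p)

    if method == "simes":
        order = np.sort(p)
        stat = float(np.min(m * order / np.arange(1, m + 1)))
        return AltCombineResult("simes", min(stat, 1.0), stat, p)

    x2 = float(-2.0 * np.sum(np.log(p)))
    if method == "fisher":
        return AltCombineResult("fisher", float(stats.chi2.sf(x2, 2 * m)), x2, p)
    if method == "brown":
        if null_p_matrix is None:
            raise ValueError("Brown's method requires a null p-value matrix")
        null_p = np.asarray(null_p_matrix, dtype=float)
        if null_p.ndim != 2 or null_p.shape[1] != m:
            raise ValueError("null_p_matrix must be R x m, columns matching pvalues")
        floor = zero_replacement if zero_replacement is not None else 1.0 / null_p.shape[0]
        null_x = -2.0 * np.log(np.clip(null_p, floor, 1.0))
        cov = np.cov(null_x, rowvar=False)
        mean = 2.0 * m  # E[-2 ln U] = 2 under uniformity
        var = float(cov.sum())
        if var <= 0:
            raise ValueError("degenerate null p-value matrix")
        c = var / (2.0 * mean)
        df = 2.0 * mean**2 / var
        return AltCombineResult("brown", float(stats.chi2.sf(x2 / c, df)), x2, p)
    raise ValueError(f"unknown combination method {method!r}")
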