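"""High-level analysis entry point: counts/tree/metadata (or ready-made
kernels) in, per-kernel and omnibus p-values out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from . import ecological_kernels as ek
from .formats_io import CountTable, SampleMetadata, harmonize
from .kernel_association_test import (
    PermutationPlan,
    SingleKernelResult,
    fit_null,
    multi_kernel_test,
)
from .omnibus import AltCombineResult, OmniKResult, combine_alt, omnik

logger = logging.getLogger("omnik")

__all__ = ["OmniKAnalysis", "omnik_test", "stacked_pvalues", "minp_statistics"]


@dataclass
class OmniKAnalysis:
    """Per-kernel results, the OmniK omnibus, and optional naive combiners."""

    per_kernel: dict[str, SingleKernelResult]
    omnibus: OmniKResult
    alt: dict[str, AltCombineResult] = field(default_factory=dict)
    R: int = 0
    seed: int | None = None
    df: int | str = "full"

    def to_dict(self) -> dict:
        out = {
            "seed": self.seed,
            "R": self.R,
            "df": self.df,
            "kernels": {label: res.summary() for label, res in self.per_kernel.items()},
            "omnibus": self.omnibus.summary(),
        }
        if self.alt:
            out["omnibus"]["method_comparisons"] = {
                name: res.pvalue for name, res in self.alt.items()
            }
        return out


def stacked_pvalues(
    results: dict[str, SingleKernelResult],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """The 3|Gamma| per-target-per-kernel observed p-values and the aligned
    R x 3|Gamma| leave-one-out null p-value matrix."""
    obs, cols, labels = [], [], []
    for measure, res in results.items():
        for target in ("M", "I", "B"):
            obs.append(res.pvalues[target])
            cols.append(res.loo_pvalues[target])
            labels.append(f"{measure}:{target}")
    return np.asarray(obs), np.column_stack(cols), labels


def minp_statistics(
    results: dict[str, SingleKernelResult],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Each kernel's min-P statistic T_h and the aligned R x |Gamma| null
    matrix of per-rearrangement minima.

    These are the per-kernel summaries that the naive Fisher / Brown / Simes
    comparisons combine across kernels as if they were p-values — the
    un-recalibrated minima are stochastically smaller than uniform, which is
    precisely what inflates the naive combiners' family-wise error relative
    to the min-P recalibration."""
    labels = list(results)
    obs = np.asarray([results[m].t_minp for m in labels])
    null = np.column_stack([results[m].minp_null for m in labels])
    return obs, null, labels


def omnik_test(
    table: CountTable | None = None,
    tree: TreeNode | None = None,
    meta: SampleMetadata | None = None,
    kernels: dict[str, ek.Kernel] | None = None,
    measures: tuple[str, ...] = ek.DEFAULT_MEASURES,
    R: int = 3000,
    df: int | str = "full",
    seed: int | None = 0,
    plan: PermutationPlan | None = None,
    alt_combiners: bool = False,
) -> OmniKAnalysis:
    """Run the full analysis.

    Either pass a count table (+ tree for phylogenetic measures) and
    metadata, in which case the requested ecological kernels are computed, or
    pass ready-made PSD ``kernels`` directly with metadata. One permutation
    plan (``R`` rearrangements, seeded) is shared by every statistic.
    """
    if meta is None:
        raise ValueError("sample metadata is required")
    if kernels is None:
        if table is None:
            raise ValueError("pass either a count table or ready-made kernels")
        table, tree, meta = harmonize(table, tree, meta)
        logger.info("computing %d ecological kernels for n=%d samples", len(measures), table.n_samples)
        distances = ek.distance_suite(table, tree, measures)
        kernels = {m: ek.distance_to_kernel(d) for m, d in distances.items()}
    n = meta.n_samples
    for label, kern in kernels.items():
        if kern.values.shape != (n, n):
            raise ValueError(f"kernel {label!r} does not match n={n}")
    null_fit = fit_null(meta)
    if plan is None:
        if seed is None:
            raise ValueError("pass a seed or an explicit permutation plan")
        plan = PermutationPlan.generate(n, R, seed)
        logger.info("permutation plan: R=%d, seed=%s", R, seed)
    results = multi_kernel_test(kernels, null_fit, meta.T, plan, df=df)
    omni = omnik(results)
    alt: dict[str, AltCombineResult] = {}
    if alt_combiners:
        obs, null_p, _ = minp_statistics(results)
        clamp = 1.0 / plan.R
        alt["fisher"] = combine_alt(obs, "fisher", zero_replacement=clamp)
        alt["brown"] = combine_alt(obs, "brown", null_p_matrix=null_p, zero_replacement=clamp)
        alt["simes"] = combine_alt(obs, "simes", zero_replacement=clamp)
    return OmniKAnalysis(
        per_kernel=results, omnibus=omni, alt=alt, R=plan.R, seed=seed, df=df
    )
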