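"""Simulation machinery: Dirichlet-multinomial microbiome counts over a
random phylogeny, phylogenetically coherent effect clusters via PAM, and
the covariate / treatment / response generators used by the type-I-error and
power experiment harnesses.

Counts are drawn from a Dirichlet-multinomial with mean proportions pi and
overdispersion theta (theta = 1/(1 + sum(gamma)); theta -> 0 recovers the
plain multinomial), total count 10 000 per sample. Responses follow

    y = a1 + T a2 + Z a3 + f(X_S) b1 + (f(X_S) . T) b2 + e      (continuous)
    logit E(y) = a1 + T a2 + Z a3 + f(X_S) b1 + (f(X_S) . T) b2 (binary)

with a1 = 0, a2 = 1, a3 = (0.5, 0.5), e ~ N(0, 1), covariates
z1 ~ Bern(0.5) and z2 = 0.5 * (row mean of the standardized abundances of a
random 10% taxon subset) + N(0, 1), and treatment T ~ Bern(0.5) in a
randomized trial or T ~ Bern(expit(0.5 (z1_std + z2_std))) in an
observational design. The affected taxa X_S are one of five PAM clusters of
the leaf cophenetic distance matrix; f standardizes abundances (linear
signal) or takes presence-absence indicators (discrete nonlinear signal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from skbio import TreeNode

from . import ecological_kernels as ek
from .formats_io import CountTable, SampleMetadata
from .kernel_association_test import (
    PermutationPlan,
    _test_from_surrogates,
    fit_null,
)
from .omnibus import combine_alt, omnik
from .surrogate_pca import SurrogateVariants, extract_surrogates

__all__ = [
    "DMParams",
    "SimulationScenario",
    "SimulatedDataset",
    "default_dm_params",
    "estimate_dm_params",
    "simulate_counts",
    "synth_tree",
    "cophenetic_matrix",
    "pam",
    "pam_effect_cluster",
    "generate_design",
    "run_experiment",
    "rejection_rates",
]

ALPHA1, ALPHA2, ALPHA3 = 0.0, 1.0, 0.5

#: effect magnitudes (b1, b2) per pattern and family
EFFECT_SIZES = {
    ("null", "gaussian"): (0.0, 0.0),
    ("null", "binomial"): (0.0, 0.0),
    ("main_only", "gaussian"): (2.0, 0.0),
    ("main_only", "binomial"): (2.0, 0.0),
    ("interaction_only", "gaussian"): (0.0, 1.0),
    ("interaction_only", "binomial"): (0.0, 3.0),
    ("both", "gaussian"): (2.0, -1.0),
    ("both", "binomial"): (-1.5, 3.0),
}


@dataclass
class DMParams:
    """Dirichlet-multinomial parameters: mean proportions, overdispersion
    theta >= 0, and the per-sample total count."""

    proportions: np.ndarray
    theta: float
    total_count: int = 10_000

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if np.any(self.proportions < 0) or not np.isclose(self.proportions.sum(), 1.0):
            raise ValueError("proportions must be a probability vector")
        if self.theta < 0:
            raise ValueError("theta must be nonnegative")

    @property
    def n_taxa(self) -> int:
        return self.proportions.shape[0]


def default_dm_params(
    p: int = 100, theta: float = 0.02, total_count: int = 10_000, seed=0
) -> DMParams:
    """Synthetic defaults: proportions are a descending-sorted flat Dirichlet
    draw (a few dominant taxa, a long rare tail), mild overdispersion."""
    rng = np.random.default_rng(seed)
    pi = np.sort(rng.dirichlet(np.ones(p)))[::-1]
    return DMParams(pi, theta, total_count)


def estimate_dm_params(table: CountTable) -> DMParams:
    """Method-of-moments estimates of proportions and overdispersion.

    Overdispersion uses the classic weighted moment estimator: with
    per-sample totals N_i and proportions p_ij,

        theta = (MSP - MSG) / (MSP + (Nc - 1) MSG)

    where MSP/MSG are the between/within mean squares pooled over taxa and
    Nc is the effective total. Negative estimates are truncated at 0.
    """
    counts = table.counts.astype(float)
    n = counts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to estimate overdispersion")
    N = counts.sum(axis=1)
    P = counts / N[:, None]
    pi = counts.sum(axis=0) / N.sum()
    msp = float(np.sum(N[:, None] * (P - pi) ** 2)) / (n - 1)
    msg = float(np.sum(N[:, None] * P * (1.0 - P))) / float(np.sum(N - 1.0))
    nc = (N.sum() - np.sum(N**2) / N.sum()) / (n - 1)
    denom = msp + (nc - 1.0) * msg
    theta = (msp - msg) / denom if denom > 0 else 0.0
    return DMParams(pi, max(theta, 0.0), int(round(N.mean())))


def simulate_counts(params: DMParams, n: int, seed) -> CountTable:
    """Draw n independent Dirichlet-multinomial count vectors."""
    rng = np.random.default_rng(seed)
    p = params.n_taxa
    if params.theta > 0:
        gamma = params.proportions * (1.0 - params.theta) / params.theta
        # per-row Dirichlet via normalized gammas; zero-concentration taxa stay zero
        g = np.where(gamma > 0, rng.gamma(np.maximum(gamma, 1e-300), size=(n, p)), 0.0)
        probs = g / g.sum(axis=1, keepdims=True)
    else:
        probs = np.broadcast_to(params.proportions, (n, p))
    counts = np.empty((n, p), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(params.total_count, probs[i])
    return CountTable(
        counts, [f"s{i+1}" for i in range(n)], [f"t{j+1}" for j in range(p)]
    )


def synth_tree(p: int, seed) -> TreeNode:
    """Random bifurcating (coalescent-style) tree over leaves t1..tp with
    positive branch lengths."""
    if p < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"t{j+1}") for j in range(p)]
    ages = [0.0] * p
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = TreeNode()
        for idx in (i, j):
            child = nodes[idx]
            child.length = max(t - ages[idx], 1e-9)
            parent.append(child)
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)] + [parent]
        ages = [a for idx, a in enumerate(ages) if idx not in (i, j)] + [t]
    root = nodes[0]
    return root


def cophenetic_matrix(tree: TreeNode, taxon_ids: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Leaf-to-leaf path-length matrix, ordered by taxon_ids."""
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    values = np.asarray(dm.data)
    if taxon_ids is not None:
        idx = [ids.index(t) for t in taxon_ids]
        values = values[np.ix_(idx, idx)]
        ids = list(taxon_ids)
    return values, ids


def pam(D: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Classic PAM (k-medoids, BUILD + SWAP) with deterministic tie-breaking
    by lowest index. Returns (medoid indices, cluster label per point)."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of points")
    # BUILD: greedily add the medoid giving the largest cost decrease
    medoids: list[int] = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = np.min(D[:, medoids], axis=1)
        best_gain, best_cand = -np.inf, -1
        for cand in range(n):
            if cand in medoids:
                continue
            gain = float(np.sum(np.maximum(current - D[:, cand], 0.0)))
            if gain > best_gain:
                best_gain, best_cand = gain, cand
        medoids.append(best_cand)
    # SWAP: accept the best strictly-improving swap until none remains
    medoids = sorted(medoids)
    cost = float(np.min(D[:, medoids], axis=1).sum())
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            others = medoids[:mi] + medoids[mi + 1 :]
            for h in range(n):
                if h in medoids:
                    continue
                trial = others + [h]
                new_cost = float(np.min(D[:, trial], axis=1).sum())
                delta = cost - new_cost
                if delta > best[0] + 1e-12:
                    best = (delta, mi, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            medoids = sorted(medoids)
            cost -= best[0]
            improved = True
    med = np.asarray(medoids)
    labels = np.argmin(D[:, med], axis=1)
    return med, labels


def pam_effect_cluster(
    tree: TreeNode, k: int = 5, cluster_id: int | str = 1, taxon_ids: list[str] | None = None
) -> list[str]:
    """Taxa of one of k PAM clusters of the cophenetic distance matrix.

    Clusters are numbered P1..Pk by ascending medoid position in the taxon
    ordering, so the labeling is deterministic for a given tree.
    """
    D, ids = cophenetic_matrix(tree, taxon_ids)
    med, labels = pam(D, k)
    if isinstance(cluster_id, str):
        cluster_id = int(cluster_id.lstrip("Pp"))
    if not 1 <= cluster_id <= k:
        raise ValueError(f"cluster_id must be in 1..{k}")
    members = np.flatnonzero(labels == cluster_id - 1)
    return [ids[i] for i in members]


@dataclass
class SimulationScenario:
    """One simulation condition: sample size, response family, treatment
    design, signal transform, effect pattern and the affected PAM cluster."""

    n: int = 100
    family: str = "gaussian"
    design: str = "rct"  # rct | observational
    f_transform: str = "standardize"  # standardize | presence_absence
    effect: str = "null"  # null | main_only | interaction_only | both
    cluster_id: int | str = 1
    n_clusters: int = 5
    p: int = 100
    theta: float = 0.02
    total_count: int = 10_000

    def __post_init__(self) -> None:
        if self.design not in ("rct", "observational"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.f_transform not in ("standardize", "presence_absence"):
            raise ValueError(f"unknown transform {self.f_transform!r}")
        if (self.effect, self.family) not in EFFECT_SIZES:
            raise ValueError(f"unknown effect/family {(self.effect, self.family)!r}")

    @property
    def beta(self) -> tuple[float, float]:
        return EFFECT_SIZES[(self.effect, self.family)]


@dataclass
class SimulatedDataset:
    table: CountTable
    tree: TreeNode
    meta: SampleMetadata
    scenario: SimulationScenario
    affected_taxa: list[str] = field(default_factory=list)
    seed: int | None = None


def _standardize(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0)
    return (M - M.mean(axis=0)) / np.where(sd > 0, sd, 1.0)


def _signal_matrix(table: CountTable, taxa: list[str], transform: str) -> np.ndarray:
    idx = [table.taxon_ids.index(t) for t in taxa]
    if transform == "presence_absence":
        return table.presence()[:, idx].astype(float)
    sub = table.proportions()[:, idx]
    sd = sub.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("constant taxa dropped from the standardized signal", stacklevel=2)
        sub = sub[:, sd > 0]
    return _standardize(sub)


def generate_design(
    table: CountTable,
    scenario: SimulationScenario,
    seed,
    affected_taxa: list[str] | None = None,
) -> SampleMetadata:
    """Covariates, treatment and response for one simulated count table."""
    rng = np.random.default_rng(seed)
    n, p = table.n_samples, table.n_taxa
    z1 = rng.binomial(1, 0.5, n).astype(float)
    n_corr = max(1, round(0.1 * p))
    corr_idx = rng.choice(p, size=n_corr, replace=False)
    xprime = _standardize(table.proportions()[:, corr_idx]).mean(axis=1)
    z2 = 0.5 * xprime + rng.normal(size=n)
    Z = np.column_stack([z1, z2])
    if scenario.design == "rct":
        T = rng.binomial(1, 0.5, n).astype(float)
    else:
        T = rng.binomial(1, expit(0.5 * _standardize(Z).sum(axis=1))).astype(float)

    lp = ALPHA1 + ALPHA2 * T + ALPHA3 * Z.sum(axis=1)
    b1_mag, b2_mag = scenario.beta
    if scenario.effect != "null":
        if affected_taxa is None:
            raise ValueError("non-null scenario needs the affected taxon cluster")
        F = _signal_matrix(table, affected_taxa, scenario.f_transform)
        p_eff = F.shape[1]
        b1 = np.full(p_eff, b1_mag)
        b2 = np.full(p_eff, b2_mag)
        if scenario.effect == "both":
            # split the cluster: first half carries main, second half interaction
            half = (p_eff + 1) // 2
            b1[half:] = 0.0
            b2[:half] = 0.0
        lp = lp + F @ b1 + (F * T[:, None]) @ b2

    if scenario.family == "gaussian":
        y = lp + rng.normal(size=n)
    else:
        for _ in range(100):
            y = rng.binomial(1, expit(lp)).astype(float)
            if not np.all(y == y[0]):
                break
        else:
            raise ValueError("degenerate binary response")
    return SampleMetadata(y, T, Z, scenario.family, list(table.sample_ids))


def simulate_dataset(
    scenario: SimulationScenario,
    seed,
    tree: TreeNode | None = None,
    dm_params: DMParams | None = None,
    affected_taxa: list[str] | None = None,
) -> SimulatedDataset:
    """Counts, tree and metadata for one scenario replicate."""
    rng = np.random.default_rng(seed)
    s1, s2, s3, s4 = rng.integers(2**31, size=4)
    if dm_params is None:
        dm_params = default_dm_params(scenario.p, scenario.theta, scenario.total_count, seed=s1)
    if tree is None:
        tree = synth_tree(dm_params.n_taxa, s2)
    table = simulate_counts(dm_params, scenario.n, s3)
    if affected_taxa is None and scenario.effect != "null":
        affected_taxa = pam_effect_cluster(
            tree, scenario.n_clusters, scenario.cluster_id, table.taxon_ids
        )
    meta = generate_design(table, scenario, s4, affected_taxa)
    return SimulatedDataset(table, tree, meta, scenario, affected_taxa or [], None)


def _gower_surrogates(
    distances: dict[str, ek.DistanceMatrix], df: int | str = "full"
) -> dict[str, SurrogateVariants]:
    """Distance -> clipped kernel -> surrogates, with a single
    eigendecomposition per kernel (the experiment hot path)."""
    out = {}
    for measure, D in distances.items():
        n = D.n
        D2 = D.values**2
        J = np.eye(n) - np.ones((n, n)) / n
        K = -0.5 * J @ D2 @ J
        out[measure] = extract_surrogates(ek.Kernel((K + K.T) / 2, measure), df=df)
    return out


def _analyze(
    surrogates: dict[str, SurrogateVariants],
    meta: SampleMetadata,
    plan: PermutationPlan,
    alt_combiners: bool,
) -> dict[str, float]:
    """P-values of every method for one replicate, from shared surrogates."""
    from .api import minp_statistics

    null_fit = fit_null(meta)
    results = {
        m: _test_from_surrogates(s, null_fit, meta.T, plan) for m, s in surrogates.items()
    }
    omni = omnik(results)
    out = {f"K:{m}": res.p_minp for m, res in results.items()}
    out.update(
        OmniK_M=omni.p_omnik_endog["M"],
        OmniK_I=omni.p_omnik_endog["I"],
        OmniK_B=omni.p_omnik_endog["B"],
        OmniK=omni.p_omnik,
    )
    if alt_combiners:
        obs, null_p, _ = minp_statistics(results)
        clamp = 1.0 / plan.R
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["fisher"] = combine_alt(obs, "fisher", zero_replacement=clamp).pvalue
            out["brown"] = combine_alt(
                obs, "brown", null_p_matrix=null_p, zero_replacement=clamp
            ).pvalue
            out["simes"] = combine_alt(obs, "simes", zero_replacement=clamp).pvalue
    return out


def run_experiment(
    scenario: SimulationScenario,
    reps: int,
    perms: int,
    seed: int,
    measures: tuple[str, ...] = ek.DEFAULT_MEASURES,
    dfs: tuple = ("full",),
    families: tuple[str, ...] | None = None,
    alt_combiners: bool = False,
    dm_params: DMParams | None = None,
) -> pd.DataFrame:
    """Replicate a scenario and collect the p-values of every method.

    The tree, Dirichlet-multinomial parameters and affected cluster are fixed
    once per experiment; counts, covariates, treatment, response and the
    permutation plan are redrawn per replicate. ``families`` may list both
    response families to test them on the same counts and kernels (they share
    everything except the response and null-model fit). Returns a tidy frame
    with columns (rep, family, df, method, pvalue).
    """
    master = np.random.default_rng(seed)
    s_dm, s_tree = master.integers(2**31, size=2)
    if dm_params is None:
        dm_params = default_dm_params(scenario.p, scenario.theta, scenario.total_count, seed=s_dm)
    tree = synth_tree(dm_params.n_taxa, s_tree)
    families = families or (scenario.family,)
    affected: list[str] | None = None
    if scenario.effect != "null":
        taxon_ids = [f"t{j+1}" for j in range(dm_params.n_taxa)]
        affected = pam_effect_cluster(tree, scenario.n_clusters, scenario.cluster_id, taxon_ids)

    rows = []
    for rep in range(reps):
        s_counts, s_design, s_plan = master.integers(2**31, size=3)
        table = simulate_counts(dm_params, scenario.n, s_counts)
        distances = ek.distance_suite(table, tree, measures)
        plan = PermutationPlan.generate(scenario.n, perms, int(s_plan))
        surro_by_df = {d: _gower_surrogates(distances, df=d) for d in dfs}
        for family in families:
            scen_f = (
                scenario
                if family == scenario.family
                else SimulationScenario(**{**scenario.__dict__, "family": family})
            )
            meta = generate_design(table, scen_f, s_design, affected)
            for d in dfs:
                pvals = _analyze(surro_by_df[d], meta, plan, alt_combiners)
                rows.extend(
                    {"rep": rep, "family": family, "df": str(d), "method": k, "pvalue": v}
                    for k, v in pvals.items()
                )
    return pd.DataFrame(rows)


def rejection_rates(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Empirical rejection rate per (family, df, method) with binomial SE."""
    def agg(g: pd.Series) -> pd.Series:
        rate = float(np.mean(g <= alpha))
        n = g.shape[0]
        return pd.Series({"rate": rate, "se": np.sqrt(rate * (1 - rate) / n), "reps": n})

    out = (
        results.groupby(["family", "df", "method"])["pvalue"].apply(agg).unstack()
    )
    return out.reset_index()
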