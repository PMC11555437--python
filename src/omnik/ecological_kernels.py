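"""Ecological beta-diversity distances and their conversion to PSD kernels.

Five measure families are supported: Jaccard (presence-absence), Bray-Curtis
(abundance), and the UniFrac family (unweighted, generalized with exponent
``alpha``, and normalized weighted), all on per-sample proportions — no
rarefaction. A distance matrix ``D`` becomes a kernel by Gower double
centering of the element-wise squared distances,

    K = -1/2 (I - 11'/n) D**2 (I - 11'/n),

followed by clipping of negative eigenvalues (Jaccard and Bray-Curtis are
not Euclidean-embeddable in general), which makes K positive semi-definite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from skbio import TreeNode

from .formats_io import CountTable

__all__ = [
    "DistanceMatrix",
    "Kernel",
    "DEFAULT_MEASURES",
    "parse_measure",
    "jaccard_distance",
    "bray_curtis_distance",
    "unifrac_distances",
    "compute_distance",
    "distance_suite",
    "distance_to_kernel",
]

#: the seven candidate measures used by the multi-kernel omnibus test
DEFAULT_MEASURES = (
    "jaccard",
    "braycurtis",
    "uwunifrac",
    "gunifrac:0.25",
    "gunifrac:0.5",
    "gunifrac:0.75",
    "wunifrac",
)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise ecological distance matrix with a measure label."""

    values: np.ndarray
    measure: str
    alpha: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-10):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(v < -1e-10):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Kernel:
    """Positive semi-definite similarity kernel derived from a distance."""

    values: np.ndarray
    measure: str
    psd_clipped: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def parse_measure(label: str) -> tuple[str, float | None]:
    """Split a measure label like ``gunifrac:0.5`` into (family, alpha)."""
    if label.startswith("gunifrac"):
        _, _, a = label.partition(":")
        alpha = float(a) if a else 0.5
        return "gunifrac", alpha
    if label in ("jaccard", "braycurtis", "uwunifrac", "wunifrac"):
        return label, None
    raise ValueError(f"unknown distance measure {label!r}")


def jaccard_distance(table: CountTable) -> DistanceMatrix:
    """Jaccard distance on presence-absence: 1 - |A∩B| / |A∪B|."""
    d = pdist(table.presence(), metric="jaccard")
    return DistanceMatrix(squareform(d), "jaccard")


def bray_curtis_distance(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on per-sample proportions."""
    d = pdist(table.proportions(), metric="braycurtis")
    return DistanceMatrix(squareform(d), "braycurtis")


def _tree_edges(tree: TreeNode, taxon_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and the taxa-by-edge descendant incidence matrix.

    Every non-root edge e contributes a column; A[j, e] = 1 when taxon j is a
    leaf descendant of the child node of e.
    """
    index = {t: i for i, t in enumerate(taxon_ids)}
    p = len(taxon_ids)
    lengths: list[float] = []
    cols: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            if node.name not in index:
                raise ValueError(f"tree leaf {node.name!r} not in table taxa")
            vec = np.zeros(p, dtype=bool)
            vec[index[node.name]] = True
        else:
            vec = np.zeros(p, dtype=bool)
            for child in node.children:
                vec |= below[id(child)]
        below[id(node)] = vec
        if node.parent is not None:
            if node.length is None:
                raise ValueError("missing branch lengths")
            lengths.append(float(node.length))
            cols.append(vec)
    return np.asarray(lengths), np.column_stack(cols).astype(float)


def unifrac_distances(
    table: CountTable,
    tree: TreeNode,
    variant: str = "unweighted",
    alpha: float | None = None,
) -> DistanceMatrix:
    """UniFrac distances: unweighted, generalized (exponent alpha), weighted.

    Unweighted is the fraction of branch length unique to either sample among
    branch length present in at least one. Weighted is the normalized
    abundance-weighted variant in [0, 1]. Generalized down-weights branches by
    (p_A + p_B)**alpha and equals normalized weighted UniFrac at alpha = 1.
    """
    if variant == "generalized":
        if alpha is None or not 0.0 <= alpha <= 1.0:
            raise ValueError("generalized UniFrac needs alpha in [0, 1]")
    elif variant not in ("unweighted", "weighted"):
        raise ValueError(f"unknown UniFrac variant {variant!r}")
    tips = {t.name for t in tree.tips()}
    missing = set(table.taxon_ids) - tips
    if missing:
        raise ValueError(f"taxon not found in tree: {sorted(missing)[0]!r}")
    b, A = _tree_edges(tree, table.taxon_ids)
    if variant == "unweighted":
        P = (table.presence().astype(float) @ A) > 0
        values = _pairwise_unweighted(b, P)
        return DistanceMatrix(values, "uwunifrac")
    P = table.proportions() @ A
    if variant == "weighted":
        values = _pairwise_generalized(b, P, 1.0)
        return DistanceMatrix(values, "wunifrac")
    values = _pairwise_generalized(b, P, alpha)
    return DistanceMatrix(values, f"gunifrac:{alpha:g}", alpha=alpha)


def _pairwise_unweighted(b: np.ndarray, P: np.ndarray) -> np.ndarray:
    n = P.shape[0]
    D = np.zeros((n, n))
    Pf = P.astype(float)
    for i in range(n - 1):
        xor = np.abs(Pf[i] - Pf[i + 1 :])
        union = np.maximum(Pf[i], Pf[i + 1 :])
        D[i, i + 1 :] = (xor @ b) / (union @ b)
    return D + D.T


def _pairwise_generalized(b: np.ndarray, P: np.ndarray, alpha: float) -> np.ndarray:
    n = P.shape[0]
    D = np.zeros((n, n))
    for i in range(n - 1):
        s = P[i] + P[i + 1 :]
        diff = np.abs(P[i] - P[i + 1 :])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(s > 0, diff / np.where(s > 0, s, 1.0), 0.0)
            w = np.where(s > 0, s**alpha, 0.0)
        num = (w * ratio) @ b
        den = w @ b
        D[i, i + 1 :] = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return D + D.T


def compute_distance(
    table: CountTable, measure: str, tree: TreeNode | None = None
) -> DistanceMatrix:
    """Compute one named distance measure ('jaccard', 'braycurtis',
    'uwunifrac', 'gunifrac:ALPHA', 'wunifrac')."""
    family, alpha = parse_measure(measure)
    if family == "jaccard":
        return jaccard_distance(table)
    if family == "braycurtis":
        return bray_curtis_distance(table)
    if tree is None:
        raise ValueError(f"measure {measure!r} requires a phylogenetic tree")
    variant = {"uwunifrac": "unweighted", "wunifrac": "weighted", "gunifrac": "generalized"}[
        family
    ]
    return unifrac_distances(table, tree, variant, alpha)


def distance_suite(
    table: CountTable,
    tree: TreeNode | None = None,
    measures: tuple[str, ...] = DEFAULT_MEASURES,
) -> dict[str, DistanceMatrix]:
    """All requested distance matrices, sharing the per-edge abundance pass
    across the UniFrac variants (the hot path of the simulation study)."""
    out: dict[str, DistanceMatrix] = {}
    unifrac = [m for m in measures if parse_measure(m)[0] in ("uwunifrac", "wunifrac", "gunifrac")]
    for m in measures:
        if m not in unifrac:
            out[m] = compute_distance(table, m, tree)
    if unifrac:
        if tree is None:
            raise ValueError("UniFrac measures require a phylogenetic tree")
        b, A = _tree_edges(tree, table.taxon_ids)
        P = table.proportions() @ A
        for m in unifrac:
            family, alpha = parse_measure(m)
            if family == "uwunifrac":
                pres = (table.presence().astype(float) @ A) > 0
                out[m] = DistanceMatrix(_pairwise_unweighted(b, pres), m)
            elif family == "wunifrac":
                out[m] = DistanceMatrix(_pairwise_generalized(b, P, 1.0), m)
            else:
                out[m] = DistanceMatrix(_pairwise_generalized(b, P, alpha), m, alpha=alpha)
    return {m: out[m] for m in measures}


def distance_to_kernel(D: DistanceMatrix, tol: float = 1e-8) -> Kernel:
    """Gower double-centering of squared distances, then PSD clipping.

    Eigenvalues below zero are set to zero and the kernel reconstructed;
    ``psd_clipped`` records whether any eigenvalue beyond numerical noise
    was removed.
    """
    n = D.n
    D2 = D.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    K = -0.5 * J @ D2 @ J
    K = (K + K.T) / 2
    eigval, eigvec = np.linalg.eigh(K)
    clipped = bool(eigval.min() < -tol * max(eigval.max(), 1.0))
    if eigval.min() < 0:
        eigval = np.clip(eigval, 0.0, None)
        K = (eigvec * eigval) @ eigvec.T
        K = (K + K.T) / 2
    return Kernel(K, D.measure, psd_clipped=clipped)


def read_square_matrix(path) -> pd.DataFrame:
    """Read a square matrix TSV with sample ids as header row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("row and column ids differ")
    return df


def write_square_matrix(values: np.ndarray, sample_ids: list[str], path) -> None:
    pd.DataFrame(values, index=sample_ids, columns=sample_ids).to_csv(path, sep="\t")
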