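"""Reading, validation and harmonization of count tables, trees and metadata.

The canonical in-memory objects are :class:`CountTable` (samples x taxa
nonnegative integer counts), a rooted :class:`skbio.TreeNode` with branch
lengths, and :class:`SampleMetadata` (response, treatment, covariates).
Sample order of the count table is canonical: :func:`harmonize` reorders
everything else to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CountTable",
    "SampleMetadata",
    "read_count_table",
    "write_count_table",
    "read_tree",
    "write_tree",
    "read_metadata",
    "harmonize",
]


@dataclass
class CountTable:
    """A samples-by-taxa table of nonnegative integer counts."""

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if not np.issubdtype(self.counts.dtype, np.number):
            raise ValueError("non-numeric counts")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if np.any(self.counts != np.floor(self.counts)):
            raise ValueError("non-integer counts")
        self.counts = self.counts.astype(np.int64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        n, p = self.counts.shape
        if n < 2 or p < 2:
            raise ValueError("need at least 2 samples and 2 taxa")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match counts")
        if len(self.taxon_ids) != p:
            raise ValueError("taxon_ids length does not match counts")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample id")
        if len(set(self.taxon_ids)) != p:
            raise ValueError("duplicate taxon id")
        if np.any(self.counts.sum(axis=1) == 0):
            raise ValueError("sample with all-zero counts")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def proportions(self) -> np.ndarray:
        """Per-sample relative abundances (rows sum to 1)."""
        totals = self.counts.sum(axis=1, keepdims=True)
        return self.counts / totals

    def presence(self) -> np.ndarray:
        """Boolean presence-absence matrix (count > 0)."""
        return self.counts > 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)


@dataclass
class SampleMetadata:
    """Response, treatment and covariates for n samples, aligned by sample id.

    ``family`` declares the response type: ``"gaussian"`` for a continuous
    response, ``"binomial"`` for a 0/1 response.
    """

    y: np.ndarray
    T: np.ndarray
    Z: np.ndarray
    family: str
    sample_ids: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.T = np.asarray(self.T, dtype=float).ravel()
        n = self.y.shape[0]
        if self.Z is None:
            self.Z = np.empty((n, 0))
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim == 1:
            self.Z = self.Z[:, None]
        if self.T.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("y, T, Z must have the same number of rows")
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        for name, arr in (("y", self.y), ("T", self.T), ("Z", self.Z)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"missing or non-finite values in {name}")
        if self.family == "binomial" and not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ValueError("binomial response must be 0/1")
        if self.sample_ids:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != n:
                raise ValueError("sample_ids length does not match rows")
            if len(set(self.sample_ids)) != n:
                raise ValueError("duplicate sample id")

    @property
    def n_samples(self) -> int:
        return self.y.shape[0]

    def subset(self, idx: np.ndarray) -> "SampleMetadata":
        ids = [self.sample_ids[i] for i in idx] if self.sample_ids else []
        return SampleMetadata(
            self.y[idx], self.T[idx], self.Z[idx], self.family, ids, list(self.covariate_names)
        )


def read_count_table(
    path: str | Path, format: str = "tsv", orientation: str = "taxa_rows"
) -> CountTable:
    """Read a count table from TSV or BIOM.

    TSV orientation must be declared (default ``taxa_rows``, the common QIIME
    export with taxa in rows and samples in columns) — it is never guessed.
    The returned table always has samples in rows.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.empty:
            raise ValueError("empty table")
        if orientation == "taxa_rows":
            df = df.T
        elif orientation != "samples_rows":
            raise ValueError(f"unknown orientation {orientation!r}")
        return CountTable(df.to_numpy(), list(df.index), list(df.columns))
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown format {format!r}")


def _read_biom(path: Path) -> CountTable:
    """Minimal BIOM reader: v1 (JSON) or v2 (HDF5). Observations are taxa."""
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic.startswith(b"\x89HDF"):
        import h5py

        with h5py.File(path, "r") as f:
            sample_ids = [s.decode() for s in f["sample/ids"][:]]
            taxon_ids = [t.decode() for t in f["observation/ids"][:]]
            # CSR over observations (taxa)
            data = f["observation/matrix/data"][:]
            indices = f["observation/matrix/indices"][:]
            indptr = f["observation/matrix/indptr"][:]
            from scipy.sparse import csr_matrix

            mat = csr_matrix(
                (data, indices, indptr), shape=(len(taxon_ids), len(sample_ids))
            ).toarray()
        return CountTable(mat.T, sample_ids, taxon_ids)
    with open(path) as fh:
        doc = json.load(fh)
    taxon_ids = [row["id"] for row in doc["rows"]]
    sample_ids = [col["id"] for col in doc["columns"]]
    mat = np.zeros((len(taxon_ids), len(sample_ids)))
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    return CountTable(mat.T, sample_ids, taxon_ids)


def write_count_table(table: CountTable, path: str | Path, orientation: str = "taxa_rows") -> None:
    df = table.to_dataframe()
    if orientation == "taxa_rows":
        df = df.T
    df.to_csv(path, sep="\t")


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted Newick tree, requiring branch lengths on every edge."""
    tree = TreeNode.read(str(path), format="newick")
    return validate_tree(tree)


def validate_tree(tree: TreeNode) -> TreeNode:
    names = []
    for node in tree.postorder(include_self=False):
        if node.length is None:
            raise ValueError("missing branch lengths")
        if node.length < 0:
            raise ValueError("negative branch length")
        if node.is_tip():
            if not node.name:
                raise ValueError("unlabeled leaf")
            names.append(node.name)
    if len(set(names)) != len(names):
        raise ValueError("duplicate leaf labels")
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_metadata(
    path: str | Path,
    response: str,
    treatment: str,
    covariates: list[str] | None = None,
    family: str = "gaussian",
) -> SampleMetadata:
    """Read sample metadata from a TSV with sample ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    covariates = covariates or []
    for col in [response, treatment, *covariates]:
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in metadata")
        if df[col].isna().any():
            raise ValueError(f"missing values in metadata column {col!r}")
    Z = df[covariates].to_numpy(dtype=float) if covariates else None
    return SampleMetadata(
        df[response].to_numpy(dtype=float),
        df[treatment].to_numpy(dtype=float),
        Z,
        family,
        [str(s) for s in df.index],
        covariates,
    )


def harmonize(
    table: CountTable, tree: TreeNode | None, meta: SampleMetadata
) -> tuple[CountTable, TreeNode | None, SampleMetadata]:
    """Restrict table and metadata to common samples, in the table's order.

    Taxa absent from the tree are an error, never silently dropped. The tree
    is returned sheared to the table's taxa so UniFrac sums only over branch
    length relevant to the observed community.
    """
    if not meta.sample_ids:
        raise ValueError("metadata has no sample ids to align on")
    meta_index = {s: i for i, s in enumerate(meta.sample_ids)}
    keep = [i for i, s in enumerate(table.sample_ids) if s in meta_index]
    if not keep:
        raise ValueError("no samples shared between count table and metadata")
    common_samples = [table.sample_ids[i] for i in keep]
    table = CountTable(table.counts[keep], common_samples, list(table.taxon_ids))
    meta = meta.subset(np.array([meta_index[s] for s in common_samples]))

    if tree is not None:
        tips = {t.name for t in tree.tips()}
        missing = [t for t in table.taxon_ids if t not in tips]
        if missing:
            raise ValueError(f"taxon not found in tree: {missing[0]!r}")
        if tips - set(table.taxon_ids):
            tree = tree.shear(table.taxon_ids)
        validate_tree(tree)
    return table, tree, meta
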