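"""Surrogate variants: principal components extracted from a kernel.

Any PSD kernel is a gram matrix of some (possibly unknown) transformed
variant matrix. Its eigendecomposition K = U D^2 U' yields X* = U D, an
n-by-df matrix of orthogonal surrogate variants with X* X*' = K, usable in
place of the unknown variants. Components with (numerically) zero
eigenvalue are dropped; column signs are fixed so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecological_kernels import Kernel

__all__ = ["SurrogateVariants", "extract_surrogates"]

#: relative eigenvalue threshold below which a component counts as zero
ZERO_EIG_RTOL = 1e-10


@dataclass
class SurrogateVariants:
    """X* = U D over the nonzero components of a kernel's eigendecomposition.

    Column j has squared norm equal to the j-th (descending) eigenvalue of
    the clipped kernel; ``singular_values`` are the diagonal of D, i.e. the
    square roots of those eigenvalues.
    """

    matrix: np.ndarray
    singular_values: np.ndarray
    measure: str = ""

    @property
    def df(self) -> int:
        return self.matrix.shape[1]

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.singular_values**2

    def reconstruct(self) -> np.ndarray:
        return self.matrix @ self.matrix.T


def extract_surrogates(K: Kernel | np.ndarray, df: int | str = "full") -> SurrogateVariants:
    """Extract surrogate variants from a PSD kernel.

    Eigenvalues <= ZERO_EIG_RTOL * lambda_max are dropped ("full" df keeps
    all surviving components); a numeric df must not exceed the surviving
    count. Each column's sign is fixed so its largest-magnitude entry is
    positive — downstream gram matrices are invariant to this choice.
    """
    measure = K.measure if isinstance(K, Kernel) else ""
    values = K.values if isinstance(K, Kernel) else np.asarray(K, dtype=float)
    eigval, eigvec = np.linalg.eigh(values)
    order = np.argsort(eigval, kind="stable")[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    lam_max = eigval[0] if eigval.size else 0.0
    if lam_max <= 0:
        raise ValueError("kernel is numerically zero: no surviving component")
    keep = eigval > ZERO_EIG_RTOL * lam_max
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    surviving = eigval.shape[0]
    if df != "full":
        df = int(df)
        if df < 1:
            raise ValueError("df must be at least 1")
        if df > surviving:
            raise ValueError(f"df={df} exceeds the {surviving} surviving components")
        eigval, eigvec = eigval[:df], eigvec[:, :df]
    # deterministic sign: largest-|entry| positive, first index on ties
    flip = eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(eigvec.shape[1])] < 0
    eigvec = eigvec * np.where(flip, -1.0, 1.0)
    sigma = np.sqrt(eigval)
    return SurrogateVariants(eigvec * sigma, sigma, measure)
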