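"""Per-bin normalization vectors.

Normalized counts are c'_ij = c_ij / (v_i * v_j). Three vector families:

* ``VC`` (vanilla coverage): v_i = row_sum_i / mean(nonzero row sums).
* ``VC_SQRT``: sqrt of VC — halves the coverage correction per axis.
* ``BALANCED``: symmetric iterative proportional scaling, the fixed point
  of v_i <- v_i * sqrt(s_i / mean(s)) where s_i is the row sum of the
  currently normalized matrix. At convergence all unmasked normalized row
  sums agree to within ``tol`` (relative).

Zero-coverage bins are masked: their factor is NaN and they are excluded
from all means. ``NONE`` is identity and is never stored; readers
synthesize all-ones vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import InternalError

NORM_NONE = "NONE"
NORM_VC = "VC"
NORM_VC_SQRT = "VC_SQRT"
NORM_BALANCED = "BALANCED"

#: Norm types stored in a container (NONE is synthesized, never stored).
STORED_NORM_TYPES = (NORM_VC, NORM_VC_SQRT, NORM_BALANCED)
NORM_TYPES = (NORM_NONE,) + STORED_NORM_TYPES

DEFAULT_TOL = 1e-5
DEFAULT_MAX_ITER = 200


@dataclass
class NormVector:
    """Per-bin scaling factors for one (norm_type, chromosome, resolution).

    ``values`` are positive where defined, NaN for filtered (zero-coverage)
    bins; length = ceil(chrom_length / resolution).
    """

    norm_type: str
    chrom_index: int
    resolution: int
    values: np.ndarray = field(repr=False)
    converged: bool = True

    def __len__(self) -> int:
        return len(self.values)


def compute_coverage_norm(row_sums: np.ndarray, variant: str = NORM_VC) -> np.ndarray:
    """Vanilla-coverage factors from per-bin coverage (full intra matrix row sums).

    Zero-coverage bins come back NaN. An all-zero chromosome yields an
    all-NaN vector (valid, not an error).
    """
    if variant not in (NORM_VC, NORM_VC_SQRT):
        raise ValueError(f"variant must be VC or VC_SQRT, got {variant!r}")
    row_sums = np.asarray(row_sums, dtype=np.float64)
    out = np.full(row_sums.shape, np.nan)
    nonzero = row_sums > 0
    if nonzero.any():
        out[nonzero] = row_sums[nonzero] / row_sums[nonzero].mean()
        if variant == NORM_VC_SQRT:
            out[nonzero] = np.sqrt(out[nonzero])
    return out


def compute_balanced_norm(
    counts,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, bool]:
    """Balance a square symmetric non-negative matrix; returns (vector, converged).

    ``counts`` may be dense or scipy-sparse. Iterates
    v <- v * sqrt(s / mean(s)) until the max relative deviation of the
    normalized row sums drops below ``tol``; on non-convergence the best
    iterate is returned with ``converged=False``. Zero-coverage bins are
    NaN and excluded from means.
    """
    K = sp.csr_matrix(counts) if not sp.issparse(counts) else counts.tocsr()
    K = K.astype(np.float64)
    n1, n2 = K.shape
    if n1 != n2:
        raise InternalError(f"balancing needs a square matrix, got {K.shape}")
    asym = abs(K - K.T)
    if asym.nnz and asym.max() > 1e-9 * max(K.max(), 1.0):
        raise InternalError("balancing needs a symmetric matrix")

    row = np.asarray(K.sum(axis=1)).ravel()
    active = row > 0
    v = np.full(n1, np.nan)
    if not active.any():
        return v, True
    v[active] = 1.0

    best_v = v.copy()
    best_dev = np.inf
    converged = False
    for _ in range(max_iter + 1):
        x = np.where(active, 1.0 / v, 0.0)
        s = K.dot(x) * x  # s_i = (1/v_i) * sum_j K_ij / v_j
        m = s[active].mean()
        dev = np.max(np.abs(s[active] / m - 1.0))
        if dev < best_dev:
            best_dev = dev
            best_v = v.copy()
        if dev < tol:
            converged = True
            break
        v[active] *= np.sqrt(s[active] / m)
    if not converged:
        v = best_v
    return v, converged


def coverage_row_sums(
    bin_x: np.ndarray, bin_y: np.ndarray, count: np.ndarray, n: int
) -> np.ndarray:
    """Row sums of the full symmetric matrix from upper-triangle records.

    Off-diagonal records contribute to both rows; diagonal records once.
    """
    row = np.bincount(bin_x, weights=count, minlength=n).astype(np.float64)
    off = bin_x != bin_y
    row += np.bincount(bin_y[off], weights=count[off], minlength=n)
    return row


def sparse_symmetric(
    bin_x: np.ndarray, bin_y: np.ndarray, count: np.ndarray, n: int
) -> sp.csr_matrix:
    """Full symmetric sparse matrix from upper-triangle (bin_x <= bin_y) records."""
    off = bin_x != bin_y
    rows = np.concatenate([bin_x, bin_y[off]])
    cols = np.concatenate([bin_y, bin_x[off]])
    vals = np.concatenate([count, count[off]])
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
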