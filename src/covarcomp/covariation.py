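"""Mutual-information covariation statistics: entropy, MI, MIp (APC) and Zpx.

The score chain is the standard one for detecting coevolving column pairs
in a protein multiple sequence alignment:

1. Shannon entropy H(i) per column and joint entropy H(i,j) per column
   pair, from raw frequency counts (no pseudocounts, no sequence weights
   — redundancy is removed upstream).
2. Mutual information MI(i,j) = H(i) + H(j) − H(i,j).
3. Average-product correction:
   MIp(i,j) = MI(i,j) − mean_i(MI)·mean_j(MI) / mean(MI),
   which subtracts the background signal from overall column entropy and
   shared ancestry.
4. Zpx: MIp(i,j) is z-scored within column i and within column j
   (off-diagonal entries only); the two z-scores are multiplied and the
   signed square root of the product is the final score.

Highly covarying pairs are those whose Zpx exceeds the alignment mean by
more than ``k`` standard deviations (default k = 2).

Entropies are in bits.  The logarithm base is immaterial for Zpx itself
because the per-column z-scoring removes scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, ColumnMask, GAP_CODE, ungapped_columns

N_SYMBOLS = 21  # 20 amino acids + gap


class DegenerateInputError(ValueError):
    """Raised when an operation is undefined for the given input size."""


def _check_gap_free(aln: Alignment, i: int) -> None:
    if (aln.codes[:, i] == GAP_CODE).any():
        raise ValueError(f"column {i} contains gaps; covariation requires gap-free columns")


def column_entropy(aln: Alignment, i: int) -> float:
    """Shannon entropy (bits) of column ``i`` from raw frequencies."""
    _check_gap_free(aln, i)
    counts = np.bincount(aln.codes[:, i], minlength=N_SYMBOLS)
    p = counts[counts > 0] / aln.n_seq
    return float(-(p * np.log2(p)).sum())


def joint_entropy(aln: Alignment, i: int, j: int) -> float:
    """Joint Shannon entropy (bits) of columns ``i`` and ``j``."""
    if i == j:
        raise ValueError("joint entropy requires two distinct columns")
    _check_gap_free(aln, i)
    _check_gap_free(aln, j)
    joint = aln.codes[:, i].astype(np.intp) * N_SYMBOLS + aln.codes[:, j]
    counts = np.bincount(joint, minlength=N_SYMBOLS * N_SYMBOLS)
    p = counts[counts > 0] / aln.n_seq
    return float(-(p * np.log2(p)).sum())


def mutual_information(aln: Alignment, i: int, j: int) -> float:
    """MI(i,j) = H(i) + H(j) − H(i,j), clamped at zero from below."""
    mi = column_entropy(aln, i) + column_entropy(aln, j) - joint_entropy(aln, i, j)
    return max(mi, 0.0)


def mi_matrix(aln: Alignment, columns: ColumnMask | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray, ColumnMask]:
    """Per-column entropies and the full MI / joint-entropy matrices.

    Returns ``(H, Hjoint, MI, columns)`` where ``H`` has shape (m,) and
    the matrices (m, m), indexed by position within the mask.  Diagonals
    of Hjoint and MI are zero by convention and excluded from all
    downstream statistics.
    """
    if columns is None:
        columns = ungapped_columns(aln)
    cols = list(columns)
    m = len(cols)
    codes = aln.codes[:, cols].astype(np.intp)
    n = aln.n_seq

    H = np.empty(m)
    for a in range(m):
        counts = np.bincount(codes[:, a], minlength=N_SYMBOLS)
        p = counts[counts > 0] / n
        H[a] = -(p * np.log2(p)).sum()

    Hjoint = np.zeros((m, m))
    for a in range(m):
        joint_base = codes[:, a] * N_SYMBOLS
        for b in range(a + 1, m):
            counts = np.bincount(joint_base + codes[:, b])
            p = counts[counts > 0] / n
            h = -(p * np.log2(p)).sum()
            Hjoint[a, b] = Hjoint[b, a] = h

    MI = H[:, None] + H[None, :] - Hjoint
    np.fill_diagonal(MI, 0.0)
    np.clip(MI, 0.0, None, out=MI)
    return H, Hjoint, MI, columns


def apc_correction(MI: np.ndarray) -> np.ndarray:
    """Average-product-corrected mutual information (MIp).

    ``MIp(i,j) = MI(i,j) − mean_i · mean_j / mean`` where the means are
    over off-diagonal entries.  Requires at least 3 columns; if the
    overall mean MI is zero, MIp is identically zero by convention.
    """
    MI = np.asarray(MI, dtype=float)
    m = MI.shape[0]
    if MI.ndim != 2 or MI.shape[1] != m:
        raise ValueError("MI must be a square matrix")
    if m < 3:
        raise DegenerateInputError("APC requires at least 3 columns")
    if not np.allclose(MI, MI.T):
        raise ValueError("MI matrix must be symmetric")
    off = ~np.eye(m, dtype=bool)
    col_mean = (MI.sum(axis=1) - np.diag(MI)) / (m - 1)
    overall = MI[off].mean()
    if overall == 0.0:
        return np.zeros_like(MI)
    MIp = MI - np.outer(col_mean, col_mean) / overall
    np.fill_diagonal(MIp, 0.0)
    return MIp


def zpx(MIp: np.ndarray) -> np.ndarray:
    """Signed-sqrt product of the two per-column z-scores of MIp.

    For pair (i,j), z_i is MIp(i,j) standardized against the off-diagonal
    entries of column i (population SD); z_j likewise.  The score is
    sign(z_i·z_j)·sqrt(|z_i·z_j|).  A column with zero SD contributes
    z = 0.
    """
    MIp = np.array(MIp, dtype=float)
    np.fill_diagonal(MIp, 0.0)
    m = MIp.shape[0]
    off = ~np.eye(m, dtype=bool)
    col_mean = MIp.sum(axis=0) / (m - 1)  # diagonal is zero
    col_sq = (MIp**2).sum(axis=0) / (m - 1)
    col_sd = np.sqrt(np.maximum(col_sq - col_mean**2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (MIp - col_mean[None, :]) / col_sd[None, :]
    z[:, col_sd == 0] = 0.0
    prod = z * z.T
    out = np.sign(prod) * np.sqrt(np.abs(prod))
    np.fill_diagonal(out, 0.0)
    out[~off] = 0.0
    return out


@dataclass(frozen=True)
class CovariationResult:
    """All per-column and per-pair covariation statistics for one alignment.

    Matrices are indexed by position within ``columns`` (the mask of
    gap-free alignment columns); ``columns`` maps back to 0-based
    alignment column indices.
    """

    columns: ColumnMask
    H: np.ndarray
    Hjoint: np.ndarray
    MI: np.ndarray
    MIp: np.ndarray
    Zpx: np.ndarray
    mean_zpx: float
    sd_zpx: float

    def pair_zpx(self, i: int, j: int) -> float:
        """Zpx for a pair of alignment column indices."""
        pos = {c: k for k, c in enumerate(self.columns)}
        return float(self.Zpx[pos[i], pos[j]])


@dataclass(frozen=True)
class CovaryingPairSet:
    """Thresholded set of highly covarying column pairs.

    ``pairs`` holds unordered (i, j) alignment-column pairs with i < j,
    all drawn from ``columns``.
    """

    pairs: frozenset[tuple[int, int]]
    columns: ColumnMask
    threshold: float
    k: float

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def compute_covariation(aln: Alignment, columns: ColumnMask | None = None) -> CovariationResult:
    """Run the full entropy → MI → MIp → Zpx chain on one alignment."""
    H, Hjoint, MI, columns = mi_matrix(aln, columns)
    MIp = apc_correction(MI)
    Z = zpx(MIp)
    m = Z.shape[0]
    iu = np.triu_indices(m, k=1)
    vals = Z[iu]
    return CovariationResult(
        columns=columns,
        H=H,
        Hjoint=Hjoint,
        MI=MI,
        MIp=MIp,
        Zpx=Z,
        mean_zpx=float(vals.mean()),
        sd_zpx=float(vals.std()),
    )


def top_covarying_pairs(result: CovariationResult, k: float = 2.0) -> CovaryingPairSet:
    """Pairs with Zpx more than ``k`` SD above the mean Zpx.

    The threshold is strict; when the Zpx landscape is flat (SD = 0) the
    set is empty, since a flat score surface carries no signal.
    """
    m = len(result.columns)
    if m * (m - 1) // 2 < 2:
        raise DegenerateInputError("need at least 2 column pairs")
    threshold = result.mean_zpx + k * result.sd_zpx
    cols = list(result.columns)
    pairs: set[tuple[int, int]] = set()
    if result.sd_zpx > 0:
        a_idx, b_idx = np.triu_indices(m, k=1)
        sel = result.Zpx[a_idx, b_idx] > threshold
        pairs = {
            (cols[a], cols[b]) for a, b in zip(a_idx[sel], b_idx[sel])
        }
    return CovaryingPairSet(
        pairs=frozenset(pairs), columns=result.columns, threshold=threshold, k=k
    )
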