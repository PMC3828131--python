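"""Per-position sequence statistics: recovery, entropy profile, profile similarity.

Profile similarity follows the two-factor structure of prof_sim-style
scores: at each column the score is the product of (1) the probability
that the two column distributions come from the same source, instantiated
as 1 − JS(p, q), and (2) the prior surprise of the merged source relative
to the background, instantiated as JS((p+q)/2, background).  JS is the
Jensen–Shannon divergence with base-2 logarithms, which is bounded in
[0, 1].  This is a JS-divergence instantiation of the published
description, not a numerical reimplementation of the original tool.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import jensenshannon

from .alignment import AMINO_ACIDS, Alignment, GAP_CODE
from .covariation import DegenerateInputError, column_entropy

N_AA = len(AMINO_ACIDS)


def sequence_recovery(designed: Alignment, native: str) -> float:
    """Mean percent identity of each row to the native sequence.

    Identity per row is (positions identical to the native, gaps never
    matching) / alignment length, averaged over rows and scaled to percent.
    """
    native = native.upper()
    if len(native) != designed.n_col:
        raise ValueError(
            f"native length {len(native)} != alignment width {designed.n_col}"
        )
    nat = np.frombuffer(native.encode(), dtype=np.uint8)
    rows = np.frombuffer(
        "".join(designed.rows).encode(), dtype=np.uint8
    ).reshape(designed.n_seq, designed.n_col)
    matches = (rows == nat[None, :]) & (rows != ord("-"))
    return float(matches.mean(axis=1).mean() * 100.0)


def entropy_profile(aln: Alignment) -> list[float | None]:
    """Column entropies in bits; gapped columns are reported as None."""
    profile: list[float | None] = []
    for i in range(aln.n_col):
        if (aln.codes[:, i] == GAP_CODE).any():
            profile.append(None)
        else:
            profile.append(column_entropy(aln, i))
    return profile


def column_frequencies(aln: Alignment, i: int) -> np.ndarray:
    """Amino-acid frequency vector (length 20) of a gap-free column."""
    codes = aln.codes[:, i]
    if (codes == GAP_CODE).any():
        raise ValueError(f"column {i} contains gaps")
    counts = np.bincount(codes, minlength=N_AA + 1)[:N_AA]
    return counts / counts.sum()


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 Jensen–Shannon divergence, bounded in [0, 1]."""
    d = jensenshannon(p, q, base=2)
    if np.isnan(d):  # identical distributions can produce 0/0 upstream
        return 0.0
    return float(d**2)  # scipy returns the square root (the JS distance)


def profile_similarity(
    a: Alignment, b: Alignment, background: np.ndarray | None = None
) -> float:
    """Mean per-column profile similarity between two aligned sequence sets.

    Per column: ``(1 − JS(p, q)) · JS(m, background)`` with m = (p+q)/2.
    The score is high only where the two column distributions agree AND
    differ from the background; it is averaged over columns that are
    gap-free in both alignments.  Background defaults to uniform.
    """
    if a.n_col != b.n_col:
        raise ValueError("alignments must have equal column counts")
    if background is None:
        background = np.full(N_AA, 1.0 / N_AA)
    background = np.asarray(background, dtype=float)
    scores = []
    for i in range(a.n_col):
        if (a.codes[:, i] == GAP_CODE).any() or (b.codes[:, i] == GAP_CODE).any():
            continue
        p = column_frequencies(a, i)
        q = column_frequencies(b, i)
        m = (p + q) / 2.0
        scores.append((1.0 - js_divergence(p, q)) * js_divergence(m, background))
    if not scores:
        raise DegenerateInputError("no mutually ungapped columns")
    return float(np.mean(scores))
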