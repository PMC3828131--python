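"""Amino-acid pair propensities at covarying position pairs.

The propensity PP(x, y) is the observed frequency of the unordered residue
pair {x, y} across all sequences and covarying position pairs, divided by
the frequency expected if residues occurred independently:
``f(x)·f(y)`` for x == y and ``2·f(x)·f(y)`` for x != y (the factor 2
because position pairs are unordered).  Cysteine is excluded from the
analysis: any residue pair containing C is dropped before normalization.

Propensities are reported as Z-scores over the defined cells of each
table, and two tables are compared by the Pearson correlation of their
Z-scores over mutually defined cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .alignment import AMINO_ACIDS, Alignment
from .covariation import CovaryingPairSet, DegenerateInputError

PROPENSITY_ALPHABET = "".join(a for a in AMINO_ACIDS if a != "C")
_IDX = {a: i for i, a in enumerate(PROPENSITY_ALPHABET)}
N = len(PROPENSITY_ALPHABET)  # 19


@dataclass(frozen=True)
class PropensityTable:
    """Symmetric pair-propensity table over the 19-letter (no-C) alphabet.

    ``counts[x, y]`` holds unordered-pair counts (upper triangle mirrored);
    ``pp`` the observed/expected ratio; ``z`` the per-cell Z-score, NaN for
    undefined cells (zero expected frequency).
    """

    alphabet: str
    counts: np.ndarray
    pp: np.ndarray
    z: np.ndarray

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.z)


def pair_propensity(
    aln: Alignment,
    pairs: CovaryingPairSet | set,
    expected_from: str = "pairs",
) -> PropensityTable:
    """Build the pair-propensity table for a set of covarying position pairs.

    ``expected_from`` selects the source of the single-residue expected
    frequencies: ``"pairs"`` (default) pools residues at the covarying
    positions themselves; ``"alignment"`` uses all gap-free residues of the
    alignment.
    """
    pair_list = sorted(set(pairs))
    if not pair_list:
        raise DegenerateInputError("empty covarying pair set")

    counts_u = np.zeros((N, N))  # unordered counts, upper triangle only
    single = np.zeros(N)
    for (i, j) in pair_list:
        for row in aln.rows:
            x, y = row[i], row[j]
            if "C" in (x, y) or "-" in (x, y):
                continue
            xi, yi = sorted((_IDX[x], _IDX[y]))
            counts_u[xi, yi] += 1
            single[_IDX[x]] += 1
            single[_IDX[y]] += 1

    total_pairs = counts_u.sum()
    if total_pairs == 0:
        raise DegenerateInputError("no cysteine-free residue pairs observed")

    if expected_from == "alignment":
        single = np.zeros(N)
        for row in aln.rows:
            for ch in row:
                if ch in _IDX:
                    single[_IDX[ch]] += 1
    elif expected_from != "pairs":
        raise ValueError("expected_from must be 'pairs' or 'alignment'")
    f = single / single.sum()

    counts = counts_u + np.triu(counts_u, k=1).T  # symmetric display copy
    f_obs = counts_u / total_pairs
    f_obs = np.triu(f_obs) + np.triu(f_obs, k=1).T

    expected = 2.0 * np.outer(f, f)
    np.fill_diagonal(expected, f**2)
    iu, ju = np.triu_indices(N)

    pp = np.full((N, N), np.nan)
    defined = expected > 0
    pp[defined] = f_obs[defined] / expected[defined]

    z = np.full((N, N), np.nan)
    cells = defined[np.triu_indices(N)]
    vals = pp[np.triu_indices(N)][cells]
    mu, sd = vals.mean(), vals.std()
    if sd > 0:
        z_tri = np.full(len(cells), np.nan)
        z_tri[cells] = (pp[np.triu_indices(N)][cells] - mu) / sd
        z[iu, ju] = z_tri
        z[ju, iu] = z_tri
    return PropensityTable(alphabet=PROPENSITY_ALPHABET, counts=counts, pp=pp, z=z)


def propensity_correlation(a: PropensityTable, b: PropensityTable) -> float:
    """Pearson r between two tables' Z-scores over mutually defined cells."""
    if a.alphabet != b.alphabet:
        raise ValueError("tables must share an alphabet")
    iu = np.triu_indices(N)
    mask = a.defined()[iu] & b.defined()[iu]
    if mask.sum() < 3:
        raise DegenerateInputError("fewer than 3 mutually defined cells")
    r, _ = pearsonr(a.z[iu][mask], b.z[iu][mask])
    return float(r)
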