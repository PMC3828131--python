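"""Comparison of two sets of highly covarying pairs.

Implements the percent-overlap similarity 2C/(A+B), its hypergeometric
significance against a shared universe of eligible column pairs, the
near/far sequence-separation split, and the three-way classification of
pairs into overlap / A-specific / B-specific sets.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from .covariation import CovaryingPairSet

Pair = tuple[int, int]


class UniverseMismatchError(ValueError):
    """Raised when two pair sets are not drawn from the same column universe."""


@dataclass(frozen=True)
class OverlapReport:
    n_a: int
    n_b: int
    n_overlap: int
    percent_overlap: float
    p_value: float
    universe: int


@dataclass(frozen=True)
class PairClassification:
    overlap: frozenset[Pair]
    a_specific: frozenset[Pair]
    b_specific: frozenset[Pair]


def _check_universe(a: CovaryingPairSet, b: CovaryingPairSet) -> None:
    if not set(a.columns) & set(b.columns):
        raise UniverseMismatchError(
            "pair sets must be drawn from overlapping column universes"
        )


def shared_universe_size(a: CovaryingPairSet, b: CovaryingPairSet) -> int:
    """Number of unordered column pairs eligible in both alignments."""
    shared = set(a.columns) & set(b.columns)
    m = len(shared)
    return m * (m - 1) // 2


def overlap_similarity(a: CovaryingPairSet | set, b: CovaryingPairSet | set) -> float:
    """Percent overlap 100·2C/(A+B); 0 by convention when both sets are empty."""
    sa, sb = set(a), set(b)
    total = len(sa) + len(sb)
    if total == 0:
        return 0.0
    return 100.0 * 2 * len(sa & sb) / total


def overlap_pvalue(a: CovaryingPairSet | set, b: CovaryingPairSet | set, universe: int) -> float:
    """Upper-tail hypergeometric P(X ≥ C) for the observed overlap.

    The population is the ``universe`` of eligible pairs, successes are
    the members of ``a``, draws the members of ``b``, and C the observed
    intersection (the tail includes C itself).
    """
    sa, sb = set(a), set(b)
    if len(sa | sb) > universe:
        raise UniverseMismatchError(
            f"universe ({universe}) smaller than the union of the two sets"
        )
    c = len(sa & sb)
    # sf(c-1) = P(X >= c)
    return float(hypergeom.sf(c - 1, universe, len(sa), len(sb)))


def compare_pair_sets(a: CovaryingPairSet, b: CovaryingPairSet) -> OverlapReport:
    """Overlap percent and significance for two sets over a shared universe.

    The universe is the set of unordered pairs of columns eligible in BOTH
    alignments (intersection of the two column masks); pairs involving a
    column eligible in only one alignment are excluded from the counts so
    both statistics share one sample space.
    """
    _check_universe(a, b)
    shared = set(a.columns) & set(b.columns)
    universe = shared_universe_size(a, b)
    sa = {p for p in a if p[0] in shared and p[1] in shared}
    sb = {p for p in b if p[0] in shared and p[1] in shared}
    return OverlapReport(
        n_a=len(sa),
        n_b=len(sb),
        n_overlap=len(sa & sb),
        percent_overlap=overlap_similarity(sa, sb),
        p_value=overlap_pvalue(sa, sb, universe),
        universe=universe,
    )


def split_near_far(pairs, cutoff: int = 10) -> tuple[set[Pair], set[Pair]]:
    """Split pairs by sequence separation: near iff |i − j| ≤ cutoff."""
    near = {(i, j) for (i, j) in pairs if abs(i - j) <= cutoff}
    far = set(pairs) - near
    return near, far


def classify_pairs(natural: CovaryingPairSet, designed: CovaryingPairSet) -> PairClassification:
    """Partition A ∪ B into overlap, A-specific and B-specific pairs."""
    _check_universe(natural, designed)
    sa, sb = set(natural), set(designed)
    return PairClassification(
        overlap=frozenset(sa & sb),
        a_specific=frozenset(sa - sb),
        b_specific=frozenset(sb - sa),
    )
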