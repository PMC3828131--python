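"""Physical mechanisms behind covariation: pair-transition scoring and
eight-class assignment.

For a covarying position pair (i, j) the residue pairs observed across the
alignment are compared via transitions: a change from pair (x, y) to pair
(a, b).  Each transition is scored with

    PT = phi(x, y) + phi(a, b) − phi(x, b) − phi(a, y)

where phi(x, y) is the phi (Matthews) correlation between the binary row
indicators [residue at i == x] and [residue at j == y].  High PT means the
two diagonal pairs co-occur far more than the cross pairs, i.e. the columns
exchange one residue pair for the other as a unit.

The top-scoring transitions per position pair are classified into one of
eight mechanism classes, tested in a fixed priority order: charge >
cation-pi > pi-pi > size > hydrogen bonding > other (hydrophobic) > other
(hydrophilic) > other (mixed).  Size compensation requires one residue to
shrink and the other to grow by at least 18 Å³ (one methyl group).

The residue annotation tables (volumes, charges, aromatics, hydrogen-bond
donors/acceptors, hydropathy) are package defaults and can be overridden.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import AMINO_ACIDS, Alignment
from .covariation import CovaryingPairSet

MECHANISM_CLASSES = (
    "charge",
    "cation_pi",
    "pi_pi",
    "size",
    "hbond",
    "other_hydrophobic",
    "other_hydrophilic",
    "other_mixed",
)

# Side-chain volumes (Å³), Zamyatnin-style standard table.
RESIDUE_VOLUMES = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

METHYL_VOLUME = 18.0  # Å³; minimum size change for a size transition


@dataclass(frozen=True)
class ResidueAnnotations:
    """Per-residue physicochemical annotation used by the classifier.

    Histidine is treated as uncharged and non-cationic by default; all
    fields can be overridden for sensitivity analyses.
    """

    volumes: dict[str, float] = field(default_factory=lambda: dict(RESIDUE_VOLUMES))
    positive: frozenset[str] = frozenset("KR")
    negative: frozenset[str] = frozenset("DE")
    cations: frozenset[str] = frozenset("KR")
    aromatics: frozenset[str] = frozenset("FWY")
    hbond_donors: frozenset[str] = frozenset("RKWNQHSTY")
    hbond_acceptors: frozenset[str] = frozenset("DENQHSTY")
    hydrophobic: frozenset[str] = frozenset("AVLIMFWCPG")
    min_size_change: float = METHYL_VOLUME

    def charge(self, r: str) -> int:
        if r in self.positive:
            return 1
        if r in self.negative:
            return -1
        return 0

    def validate(self) -> None:
        for r in AMINO_ACIDS:
            if r not in self.volumes or self.volumes[r] <= 0:
                raise ValueError(f"residue {r} lacks a positive volume annotation")


DEFAULT_ANNOTATIONS = ResidueAnnotations()


@dataclass(frozen=True)
class TransitionRecord:
    position_pair: tuple[int, int]
    from_pair: tuple[str, str]
    to_pair: tuple[str, str]
    score: float
    mechanism: str


def pair_phi(aln: Alignment, i: int, j: int, x: str, y: str) -> float:
    """Phi correlation of the indicators [col i == x] and [col j == y].

    Returns 0 when either indicator is constant across sequences.
    """
    col_i = np.frombuffer("".join(r[i] for r in aln.rows).encode(), dtype=np.uint8)
    col_j = np.frombuffer("".join(r[j] for r in aln.rows).encode(), dtype=np.uint8)
    u = col_i == ord(x)
    v = col_j == ord(y)
    n11 = int((u & v).sum())
    n10 = int((u & ~v).sum())
    n01 = int((~u & v).sum())
    n00 = int((~u & ~v).sum())
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        return 0.0
    return (n11 * n00 - n10 * n01) / np.sqrt(denom)


def transition_score(
    phi, i: int, j: int, x: str, y: str, a: str, b: str
) -> float:
    """PT = phi(x,y) + phi(a,b) − phi(x,b) − phi(a,y).

    ``phi`` is a callable (i, j, x, y) -> correlation, normally a cached
    wrapper around :func:`pair_phi`.
    """
    return phi(i, j, x, y) + phi(i, j, a, b) - phi(i, j, x, b) - phi(i, j, a, y)


def _has_cation_pi(p: tuple[str, str], ann: ResidueAnnotations) -> bool:
    u, v = p
    return (u in ann.cations and v in ann.aromatics) or (
        v in ann.cations and u in ann.aromatics
    )


def _has_pi_pi(p: tuple[str, str], ann: ResidueAnnotations) -> bool:
    return p[0] in ann.aromatics and p[1] in ann.aromatics


def _has_hbond(p: tuple[str, str], ann: ResidueAnnotations) -> bool:
    u, v = p
    return (u in ann.hbond_donors and v in ann.hbond_acceptors) or (
        v in ann.hbond_donors and u in ann.hbond_acceptors
    )


def classify_transition(
    x: str, y: str, a: str, b: str,
    annotations: ResidueAnnotations = DEFAULT_ANNOTATIONS,
) -> str:
    """Assign the first matching mechanism class in priority order.

    The classification is symmetric under swapping the two residue pairs
    and under swapping the two positions ((x,y,a,b) -> (y,x,b,a)).
    """
    ann = annotations
    for r in (x, y, a, b):
        if r not in ann.volumes:
            raise KeyError(f"residue {r!r} is not annotated")
    p1, p2 = (x, y), (a, b)
    cx, cy, ca, cb = (ann.charge(r) for r in (x, y, a, b))

    opposite1 = cx * cy == -1
    opposite2 = ca * cb == -1
    uncharged1 = cx == 0 and cy == 0
    uncharged2 = ca == 0 and cb == 0
    swaps_sign = opposite1 and opposite2 and ca == -cx and cb == -cy
    to_uncharged = (opposite1 and uncharged2) or (opposite2 and uncharged1)
    avoids_like = (cx != 0 and cx == cb) or (cy != 0 and cy == ca)
    if swaps_sign or to_uncharged or avoids_like:
        return "charge"

    if _has_cation_pi(p1, ann) != _has_cation_pi(p2, ann):
        return "cation_pi"

    if _has_pi_pi(p1, ann) != _has_pi_pi(p2, ann):
        return "pi_pi"

    d1 = ann.volumes[a] - ann.volumes[x]  # change at position i
    d2 = ann.volumes[b] - ann.volumes[y]  # change at position j
    t = ann.min_size_change
    if (d1 >= t and d2 <= -t) or (d1 <= -t and d2 >= t):
        return "size"

    if _has_hbond(p1, ann) != _has_hbond(p2, ann):
        return "hbond"

    hydro = [r in ann.hydrophobic for r in (x, y, a, b)]
    if all(hydro):
        return "other_hydrophobic"
    if not any(hydro):
        return "other_hydrophilic"
    return "other_mixed"


def observed_residue_pairs(
    aln: Alignment, i: int, j: int, min_count: int = 1
) -> list[tuple[str, str]]:
    """Ordered residue pairs observed ≥ ``min_count`` times at (i, j)."""
    counts = Counter(
        (r[i], r[j]) for r in aln.rows if "-" not in (r[i], r[j])
    )
    return sorted(p for p, c in counts.items() if c >= min_count)


def top_transitions(
    aln: Alignment,
    pairs: CovaryingPairSet | set,
    n: int = 10,
    annotations: ResidueAnnotations = DEFAULT_ANNOTATIONS,
    min_fraction: float = 0.01,
) -> dict[tuple[int, int], list[TransitionRecord]]:
    """Top-``n`` pair transitions by PT score for each covarying position pair.

    Candidate transitions run between residue pairs recurrently observed at
    the position pair — in at least ``max(2, ceil(min_fraction · n_seq))``
    sequences.  The support floor keeps phi estimates grounded: a residue
    pair seen once contributes a correlation fitted to a single row and
    floods the ranking with artifacts.  Set ``min_fraction = 0`` to admit
    every observed pair (then the floor is a single observation).

    Each unordered transition is reported once, oriented with the
    lexicographically smaller residue pair first.  Ties in PT break
    lexicographically on (x, y, a, b).  A position pair with fewer than 2
    eligible residue pairs yields an empty list.
    """
    if min_fraction > 0:
        min_count = max(2, int(np.ceil(min_fraction * aln.n_seq)))
    else:
        min_count = 1
    out: dict[tuple[int, int], list[TransitionRecord]] = {}
    for (i, j) in sorted(set(pairs)):
        observed = observed_residue_pairs(aln, i, j, min_count=min_count)
        cache: dict[tuple[str, str], float] = {}

        def phi(pi, pj, px, py):
            key = (px, py)
            if key not in cache:
                cache[key] = pair_phi(aln, pi, pj, px, py)
            return cache[key]

        candidates = []
        for ai in range(len(observed)):
            for bi in range(ai + 1, len(observed)):
                (x, y), (a, b) = observed[ai], observed[bi]
                pt = transition_score(phi, i, j, x, y, a, b)
                candidates.append((x, y, a, b, pt))
        candidates.sort(key=lambda c: (-c[4], c[:4]))
        out[(i, j)] = [
            TransitionRecord(
                position_pair=(i, j),
                from_pair=(x, y),
                to_pair=(a, b),
                score=pt,
                mechanism=classify_transition(x, y, a, b, annotations),
            )
            for x, y, a, b, pt in candidates[:n]
        ]
    return out


def pair_mechanism(records: list[TransitionRecord]) -> str | None:
    """Consensus mechanism over a position pair's top transitions.

    Classes vote with weight max(PT, 0), so the transitions that actually
    carry the covariation signal decide the label rather than a head count
    of weak runners-up.  When every score is non-positive the vote falls
    back to plain counts.  Ties resolve to the higher-priority class; None
    for an empty list.
    """
    if not records:
        return None
    weights: Counter = Counter()
    for r in records:
        weights[r.mechanism] += max(r.score, 0.0)
    if max(weights.values()) == 0.0:
        weights = Counter(r.mechanism for r in records)
    best = max(weights.values())
    for cls in MECHANISM_CLASSES:
        if weights.get(cls, 0) == best:
            return cls
    return None  # unreachable


def mechanism_distribution(records: list[TransitionRecord]) -> dict[str, float]:
    """Fraction of transitions per mechanism class, summing to 1."""
    if not records:
        raise ValueError("no transition records to summarize")
    counts = Counter(r.mechanism for r in records)
    total = sum(counts.values())
    return {cls: counts.get(cls, 0) / total for cls in MECHANISM_CLASSES}


def mechanism_overlap(
    a: dict[tuple[int, int], list[TransitionRecord]],
    b: dict[tuple[int, int], list[TransitionRecord]],
) -> dict[str, float | None]:
    """Percent overlap 2C/(A+B) per mechanism class between two sources.

    A position pair belongs to class m if its majority mechanism is m.
    Classes absent from both sources are reported as None.
    """
    cls_a = {p: pair_mechanism(r) for p, r in a.items() if r}
    cls_b = {p: pair_mechanism(r) for p, r in b.items() if r}
    out: dict[str, float | None] = {}
    for cls in MECHANISM_CLASSES:
        pa = {p for p, m in cls_a.items() if m == cls}
        pb = {p for p, m in cls_b.items() if m == cls}
        if not pa and not pb:
            out[cls] = None
        else:
            out[cls] = 100.0 * 2 * len(pa & pb) / (len(pa) + len(pb))
    return out
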