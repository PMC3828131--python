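"""Synthetic alignments with planted covariation and toy structures.

The generator emulates the statistical structure the covariation pipeline
assumes: independent background columns drawn from a natural amino-acid
frequency distribution, plus a chosen set of planted column pairs coupled
through a two-state model.  Each coupling names the physical mechanism it
imitates — a charge swap (RE/DR), size compensation (IA/VV) or hydrogen
bonding (AP/SS) — so the mechanism classifier can be exercised end to end.
Optional per-position substitution noise, duplicated sequences and gap
noise emulate the imperfections of real alignments.

The two-state coupling admits a closed-form mutual information (the binary
entropy of the state balance), which makes the generator usable as an
oracle in tests.

Toy structures are pseudo-residue chains (N/CA/C/CB atoms) along a
self-avoiding random walk, post-adjusted so planted pairs are spatially
proximal (< 6 Å minimum heavy-atom distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import AMINO_ACIDS, Alignment
from .structure import Residue, StructureModel, min_heavy_atom_distance

# Robinson & Robinson natural amino-acid background frequencies,
# ordered as AMINO_ACIDS (ACDEFGHIKLMNPQRSTVWY), normalized.
_RR = np.array([
    0.078, 0.019, 0.054, 0.063, 0.039, 0.074, 0.022, 0.051, 0.057, 0.090,
    0.022, 0.045, 0.052, 0.043, 0.051, 0.071, 0.058, 0.064, 0.013, 0.032,
])
NATURAL_BACKGROUND = _RR / _RR.sum()


@dataclass(frozen=True)
class CouplingModel:
    """Two-state coupling for a planted column pair.

    Sequences carry either ``state1 = (x, y)`` or ``state2 = (a, b)`` at
    the planted positions; the residues differ at both positions so the
    pair's mutual information (noise-free) is the binary entropy of the
    state balance.
    """

    name: str
    state1: tuple[str, str]
    state2: tuple[str, str]

    def __post_init__(self) -> None:
        for s in (*self.state1, *self.state2):
            if s not in AMINO_ACIDS:
                raise ValueError(f"invalid residue {s!r} in coupling state")
        if self.state1[0] == self.state2[0] or self.state1[1] == self.state2[1]:
            raise ValueError("coupling states must differ at both positions")


CHARGE_SWAP = CouplingModel("charge_swap", ("R", "E"), ("D", "R"))
SIZE_COMP = CouplingModel("size_comp", ("I", "A"), ("V", "V"))
HBOND = CouplingModel("hbond", ("A", "P"), ("S", "S"))

COUPLINGS = {c.name: c for c in (CHARGE_SWAP, SIZE_COMP, HBOND)}


def generic_two_state(state1: tuple[str, str], state2: tuple[str, str]) -> CouplingModel:
    return CouplingModel("generic_two_state", state1, state2)


def default_planted_pairs(n_col: int) -> tuple[tuple[int, int, CouplingModel], ...]:
    """One pair per mechanism, spread across ``n_col`` columns with
    disjoint position support."""
    couplings = (CHARGE_SWAP, SIZE_COMP, HBOND)
    pairs = []
    for k, coupling in enumerate(couplings):
        i, j = k, n_col // 2 + k
        if i < j < n_col:
            pairs.append((i, j, coupling))
    return tuple(pairs)


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for one synthetic alignment.

    Defaults reproduce the standard study conditions used throughout the
    test suite: 500 sequences × 50 columns, three planted pairs (one per
    mechanism), balanced states, 5% substitution noise.
    """

    n_seq: int = 500
    n_col: int = 50
    background: np.ndarray = field(
        default_factory=lambda: NATURAL_BACKGROUND.copy()
    )
    planted_pairs: tuple[tuple[int, int, CouplingModel], ...] = (
        (5, 20, CHARGE_SWAP),
        (10, 35, SIZE_COMP),
        (15, 44, HBOND),
    )
    state_balance: float = 0.5
    noise: float = 0.05
    redundancy: float = 0.0
    gap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.state_balance < 1.0:
            raise ValueError("state_balance must be in (0, 1)")
        if not 0.0 <= self.noise < 0.5:
            raise ValueError("noise must be in [0, 0.5)")
        used: set[int] = set()
        for (i, j, _) in self.planted_pairs:
            if not (0 <= i < self.n_col and 0 <= j < self.n_col):
                raise ValueError(f"planted position ({i}, {j}) outside columns")
            if i == j or i in used or j in used:
                raise ValueError("planted pairs must have disjoint position support")
            used.update((i, j))

    def planted_positions(self) -> set[int]:
        return {p for (i, j, _) in self.planted_pairs for p in (i, j)}

    def planted_pair_set(self) -> set[tuple[int, int]]:
        return {(min(i, j), max(i, j)) for (i, j, _) in self.planted_pairs}


def generate_alignment(spec: SyntheticSpec) -> Alignment:
    """Sample one alignment from a :class:`SyntheticSpec`, deterministically
    for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    n_dup = int(round(spec.redundancy * spec.n_seq))
    n_base = spec.n_seq - n_dup

    chars = rng.choice(aa, size=(n_base, spec.n_col), p=spec.background)
    for (i, j, coupling) in spec.planted_pairs:
        in_state1 = rng.random(n_base) < spec.state_balance
        chars[:, i] = np.where(in_state1, coupling.state1[0], coupling.state2[0])
        chars[:, j] = np.where(in_state1, coupling.state1[1], coupling.state2[1])
    if spec.noise > 0:
        sub_mask = rng.random(chars.shape) < spec.noise
        chars[sub_mask] = rng.choice(aa, size=int(sub_mask.sum()), p=spec.background)
    if spec.gap_fraction > 0:
        gap_mask = rng.random(chars.shape) < spec.gap_fraction
        chars[gap_mask] = "-"

    rows = ["".join(r) for r in chars]
    if n_dup > 0:
        src = rng.integers(0, n_base, size=n_dup)
        rows.extend(rows[s] for s in src)
    ids = tuple(f"seq_{k + 1:05d}" for k in range(len(rows)))
    return Alignment(ids=ids, rows=tuple(rows))


def generate_alignment_pair(
    spec: SyntheticSpec, shared_fraction: float
) -> tuple[Alignment, Alignment]:
    """Two independent alignments whose planted-pair sets overlap in
    exactly ``round(shared_fraction × count)`` position pairs.

    The first alignment uses ``spec`` as given; the second keeps the
    shared planted pairs and re-plants the remainder at fresh, disjoint
    positions with the same coupling models.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    n_pairs = len(spec.planted_pairs)
    n_shared = int(round(shared_fraction * n_pairs))

    shared = spec.planted_pairs[:n_shared]
    forbidden = spec.planted_positions()
    free = [c for c in range(spec.n_col) if c not in forbidden]
    rng.shuffle(free)
    replanted = []
    for (_, _, coupling) in spec.planted_pairs[n_shared:]:
        if len(free) < 2:
            raise ValueError("not enough free columns to re-plant pairs")
        i, j = sorted((free.pop(), free.pop()))
        replanted.append((i, j, coupling))

    seed_a, seed_b = rng.integers(0, 2**31 - 1, size=2)
    spec_a = replace(spec, seed=int(seed_a))
    spec_b = replace(
        spec, planted_pairs=tuple(shared) + tuple(replanted), seed=int(seed_b)
    )
    return generate_alignment(spec_a), generate_alignment(spec_b)


def _residue(index: int, ca: np.ndarray, direction: np.ndarray, up: np.ndarray) -> Residue:
    """Pseudo-residue with backbone-like N/CA/C and a CB off the axis."""
    n = ca - 1.46 * direction
    c = ca + 1.52 * direction
    cb = ca + 1.53 * up
    return Residue(
        name="ALA",
        chain="A",
        seqid=index + 1,
        atom_names=("N", "CA", "C", "CB"),
        elements=("N", "C", "C", "C"),
        coords=np.asarray([n, ca, c, cb], dtype=float),
    )


def generate_structure(
    n_col: int,
    planted_pairs: set[tuple[int, int]] | list[tuple[int, int]] = (),
    seed: int = 0,
    contact_distance: float = 4.5,
) -> StructureModel:
    """Toy pseudo-residue chain with planted pairs brought into contact.

    Cα positions follow a self-avoiding random walk (3.8 Å steps, ≥ 3.5 Å
    between non-adjacent residues); afterwards, the second residue of each
    planted pair is relocated next to the first so the pair's minimum
    heavy-atom distance is below 6 Å.
    """
    rng = np.random.default_rng(seed)
    planted = [(min(i, j), max(i, j)) for (i, j) in planted_pairs]
    for (i, j) in planted:
        if not (0 <= i < n_col and 0 <= j < n_col):
            raise ValueError(f"planted pair ({i}, {j}) outside chain")

    cas = [np.zeros(3)]
    for _ in range(1, n_col):
        for attempt in range(200):
            step = rng.normal(size=3)
            step = 3.8 * step / np.linalg.norm(step)
            cand = cas[-1] + step
            others = np.asarray(cas[:-1]) if len(cas) > 1 else np.empty((0, 3))
            if len(others) == 0 or np.linalg.norm(others - cand, axis=1).min() >= 3.5:
                cas.append(cand)
                break
        else:
            raise RuntimeError("self-avoiding walk failed; try another seed")
    cas = np.asarray(cas)

    # relocate planted partners into contact
    for (i, j) in planted:
        for attempt in range(500):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cand = cas[i] + contact_distance * direction
            others = np.delete(cas, j, axis=0)
            d = np.linalg.norm(others - cand, axis=1)
            if d.min() >= 3.0:
                cas[j] = cand
                break
        else:
            raise RuntimeError("could not place planted pair in contact")

    residues = []
    for k in range(n_col):
        nxt = cas[min(k + 1, n_col - 1)] - cas[max(k - 1, 0)]
        direction = nxt / max(np.linalg.norm(nxt), 1e-9)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(direction @ ref) > 0.95:
            ref = np.array([1.0, 0.0, 0.0])
        up = np.cross(direction, ref)
        up /= np.linalg.norm(up)
        residues.append(_residue(k, cas[k], direction, up))
    model = StructureModel(residues=tuple(residues))

    for (i, j) in planted:  # construction guarantee
        assert min_heavy_atom_distance(model, i, j) < 6.0
    return model


def generate_ensemble(
    base: StructureModel, n_models: int = 10, jitter_sd: float = 0.5, seed: int = 0
) -> list[StructureModel]:
    """Ensemble of copies of ``base`` with isotropic Gaussian atom jitter."""
    rng = np.random.default_rng(seed)
    ensemble = []
    for _ in range(n_models):
        residues = []
        for r in base.residues:
            noise = rng.normal(scale=jitter_sd, size=r.coords.shape) if jitter_sd > 0 else 0.0
            residues.append(
                Residue(
                    name=r.name,
                    chain=r.chain,
                    seqid=r.seqid,
                    atom_names=r.atom_names,
                    elements=r.elements,
                    coords=r.coords + noise,
                )
            )
        ensemble.append(StructureModel(residues=tuple(residues)))
    return ensemble
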