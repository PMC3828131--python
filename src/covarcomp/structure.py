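"""Structural context for covarying pairs: burial, contact distances,
interface/active-site flags and ensemble structural variation.

Burial follows the Cβ-neighbor convention: a position's burial is the
number of other residues' Cβ atoms within 8 Å of its own Cβ, binned as
exposed (0–8), intermediate (9–14) or buried (>14).  Glycine, which has no
Cβ, gets a virtual Cβ built from ideal backbone geometry.  Pair distances
are minimum heavy-atom (non-hydrogen) distances.  Interface and active
site positions are those with any heavy atom within 6 Å of a partner /
catalytic heavy atom.  Ensemble structural variation is the mean pairwise
Cα RMSD after optimal (Kabsch) superposition over a random sample of
ensemble members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

BURIAL_CUTOFF = 8.0  # Å, Cβ neighbor shell
INTERFACE_CUTOFF = 6.0  # Å, heavy-atom rule
EXPOSED_MAX = 8
INTERMEDIATE_MAX = 14

# Virtual Cβ from backbone N/CA/C, ideal tetrahedral geometry.
_CB_COEFF = (-0.58273431, 0.56802827, -0.54067466)


class MissingDensityError(ValueError):
    """A residue required for a distance is absent or has no heavy atoms."""


@dataclass(frozen=True)
class Residue:
    name: str
    chain: str
    seqid: int
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3)

    def heavy_coords(self) -> np.ndarray:
        mask = [e.upper() != "H" for e in self.elements]
        return self.coords[mask]

    def atom(self, name: str) -> np.ndarray | None:
        for n, xyz in zip(self.atom_names, self.coords):
            if n == name:
                return xyz
        return None


@dataclass(frozen=True)
class StructureModel:
    """An ordered chain of residues with an optional residue→column map.

    ``column_map`` maps 0-based residue indices to 0-based alignment
    columns; by default residue k maps to column k.
    """

    residues: tuple[Residue, ...]
    column_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cm = self.column_map or {k: k for k in range(len(self.residues))}
        if len(set(cm.values())) != len(cm):
            raise ValueError("residue-to-column map must be injective")
        object.__setattr__(self, "column_map", cm)
        for r in self.residues:
            if not np.isfinite(r.coords).all():
                raise ValueError(f"non-finite coordinates in residue {r.seqid}")

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        cas = []
        for r in self.residues:
            ca = r.atom("CA")
            if ca is None:
                raise MissingDensityError(f"residue {r.seqid} has no CA atom")
            cas.append(ca)
        return np.asarray(cas)


def read_structure(path: str | Path, column_map: dict[int, int] | None = None) -> StructureModel:
    """Read the first model of a PDB file into a StructureModel.

    Alternate locations are reduced to the highest-occupancy conformer;
    waters are dropped.
    """
    st = gemmi.read_structure(str(path))
    st.remove_alternative_conformations()
    st.remove_waters()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    residues = []
    for chain in st[0]:
        for res in chain:
            names, elements, coords = [], [], []
            for atom in res:
                names.append(atom.name)
                elements.append(atom.element.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            residues.append(
                Residue(
                    name=res.name,
                    chain=chain.name,
                    seqid=res.seqid.num,
                    atom_names=tuple(names),
                    elements=tuple(elements),
                    coords=np.asarray(coords, dtype=float),
                )
            )
    return StructureModel(residues=tuple(residues), column_map=column_map or {})


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as a single-model PDB file."""
    st = gemmi.Structure()
    st.name = "model"
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for r in model.residues:
        if r.chain not in chains:
            chains[r.chain] = gemmi.Chain(r.chain)
        res = gemmi.Residue()
        res.name = r.name
        res.seqid = gemmi.SeqId(r.seqid, " ")
        for name, el, xyz in zip(r.atom_names, r.elements, r.coords):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(el)
            atom.pos = gemmi.Position(*map(float, xyz))
            res.add_atom(atom)
        chains[r.chain].add_residue(res)
    for ch in chains.values():
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


def load_residue_map(path: str | Path) -> dict[int, int]:
    """Read a two-column TSV of 1-based residue index → 1-based column."""
    cm: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("residue"):
                continue
            res_s, col_s = line.split("\t")[:2]
            cm[int(res_s) - 1] = int(col_s) - 1
    return cm


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal-geometry Cβ position from backbone N, CA and C atoms."""
    b = ca - n
    c_vec = c - ca
    a = np.cross(b, c_vec)
    k1, k2, k3 = _CB_COEFF
    return k1 * a + k2 * b + k3 * c_vec + ca


def cbeta_position(res: Residue) -> np.ndarray:
    """A residue's Cβ, or a virtual Cβ (glycine / missing CB)."""
    cb = res.atom("CB")
    if cb is not None:
        return cb
    n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
    if n is None or ca is None or c is None:
        raise MissingDensityError(
            f"residue {res.seqid} lacks CB and complete backbone for a virtual CB"
        )
    return virtual_cbeta(n, ca, c)


def cb_neighbor_counts(model: StructureModel, cutoff: float = BURIAL_CUTOFF) -> np.ndarray:
    """Per-residue count of other residues' Cβ atoms within ``cutoff`` Å.

    The distance test is strict (< cutoff) and a residue's own Cβ is not
    counted.
    """
    cbs = np.asarray([cbeta_position(r) for r in model.residues])
    d = np.linalg.norm(cbs[:, None, :] - cbs[None, :, :], axis=-1)
    within = d < cutoff
    np.fill_diagonal(within, False)
    return within.sum(axis=1)


def burial_class(cb_count: int) -> str:
    """exposed for 0–8 neighbors, intermediate for 9–14, buried for >14."""
    if cb_count < 0:
        raise ValueError("neighbor count must be non-negative")
    if cb_count <= EXPOSED_MAX:
        return "exposed"
    if cb_count <= INTERMEDIATE_MAX:
        return "intermediate"
    return "buried"


_PAIR_BURIAL = {
    frozenset(["buried"]): "buried",
    frozenset(["buried", "intermediate"]): "buried",
    frozenset(["exposed", "buried"]): "intermediate",
    frozenset(["intermediate"]): "intermediate",
    frozenset(["exposed", "intermediate"]): "exposed",
    frozenset(["exposed"]): "exposed",
}


def pair_burial_class(a: str, b: str) -> str:
    """Six-way symmetric mapping of two burial classes to a pair class."""
    try:
        return _PAIR_BURIAL[frozenset([a, b])]
    except KeyError:
        raise ValueError(f"invalid burial classes: {a!r}, {b!r}") from None


def min_heavy_atom_distance(model: StructureModel, i: int, j: int) -> float:
    """Minimum distance (Å) between heavy atoms of residues ``i`` and ``j``."""
    try:
        ra, rb = model.residues[i], model.residues[j]
    except IndexError:
        raise MissingDensityError(f"residue index out of range: {i}, {j}") from None
    ca_, cb_ = ra.heavy_coords(), rb.heavy_coords()
    if len(ca_) == 0 or len(cb_) == 0:
        raise MissingDensityError(f"no heavy atoms for residue pair ({i}, {j})")
    d = np.linalg.norm(ca_[:, None, :] - cb_[None, :, :], axis=-1)
    return float(d.min())


def interface_positions(
    model: StructureModel, partner_atoms: np.ndarray, cutoff: float = INTERFACE_CUTOFF
) -> np.ndarray:
    """Boolean flag per residue: any heavy atom within ``cutoff`` Å of any
    partner heavy atom.  Reused with catalytic-residue atoms to flag active
    sites.  The distance test is strict (< cutoff).
    """
    partner_atoms = np.asarray(partner_atoms, dtype=float)
    if partner_atoms.size == 0:
        raise ValueError("partner atom set is empty")
    flags = np.zeros(len(model.residues), dtype=bool)
    for k, res in enumerate(model.residues):
        heavy = res.heavy_coords()
        if len(heavy) == 0:
            continue
        d = np.linalg.norm(heavy[:, None, :] - partner_atoms[None, :, :], axis=-1)
        flags[k] = bool((d < cutoff).any())
    return flags


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """RMSD between two point sets after optimal rigid superposition.

    Standard Kabsch algorithm: center both sets, rotate ``p`` onto ``q``
    with the SVD-derived proper rotation, and return the residual RMSD.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("point sets must have identical shapes")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    diff = (rot @ pc.T).T - qc
    return float(np.sqrt((diff**2).sum() / len(p)))


def structural_variation(
    ensemble: list[StructureModel], sample: int = 10, seed: int | None = None
) -> float:
    """Mean pairwise Cα RMSD over a random sample of ensemble members."""
    if len(ensemble) < 2:
        raise ValueError("ensemble must contain at least 2 models")
    n_res = {len(m) for m in ensemble}
    if len(n_res) != 1:
        raise ValueError("ensemble models must share a residue count")
    rng = np.random.default_rng(seed)
    k = min(sample, len(ensemble))
    idx = rng.choice(len(ensemble), size=k, replace=False)
    cas = [ensemble[i].ca_coords() for i in idx]
    rmsds = [
        kabsch_rmsd(cas[a], cas[b])
        for a in range(k)
        for b in range(a + 1, k)
    ]
    return float(np.mean(rmsds))


@dataclass(frozen=True)
class StructureContext:
    """Per-position and per-pair structural annotation for reporting."""

    cb_count: np.ndarray
    burial: tuple[str, ...]
    interface: np.ndarray | None
    active_site: np.ndarray | None


def build_context(
    model: StructureModel,
    partner_atoms: np.ndarray | None = None,
    catalytic_atoms: np.ndarray | None = None,
) -> StructureContext:
    counts = cb_neighbor_counts(model)
    return StructureContext(
        cb_count=counts,
        burial=tuple(burial_class(int(c)) for c in counts),
        interface=(
            interface_positions(model, partner_atoms)
            if partner_atoms is not None
            else None
        ),
        active_site=(
            interface_positions(model, catalytic_atoms)
            if catalytic_atoms is not None
            else None
        ),
    )
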