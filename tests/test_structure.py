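"""Burial classes, pair distances, interface flags and Kabsch RMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import covarcomp as cc
from covarcomp.structure import (
    MissingDensityError,
    Residue,
    StructureModel,
    build_context,
    cbeta_position,
    kabsch_rmsd,
    virtual_cbeta,
    write_pdb,
)

from oracles import min_distance_oracle


def point_residue(seqid, xyz, name="ALA", atom="CB", element="C"):
    return Residue(
        name=name, chain="A", seqid=seqid,
        atom_names=(atom,), elements=(element,),
        coords=np.array([xyz], dtype=float),
    )


class TestBurial:
    @pytest.mark.parametrize(
        "count, expected",
        [
            (0, "exposed"), (8, "exposed"),
            (9, "intermediate"), (10, "intermediate"), (14, "intermediate"),
            (15, "buried"), (30, "buried"),
        ],
    )
    def test_bins(self, count, expected):
        assert cc.burial_class(count) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cc.burial_class(-1)

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("buried", "buried", "buried"),
            ("buried", "intermediate", "buried"),
            ("exposed", "buried", "intermediate"),
            ("intermediate", "intermediate", "intermediate"),
            ("exposed", "intermediate", "exposed"),
            ("exposed", "exposed", "exposed"),
        ],
    )
    def test_pair_mapping(self, a, b, expected):
        assert cc.pair_burial_class(a, b) == expected
        assert cc.pair_burial_class(b, a) == expected  # symmetric

    def test_cb_counts_strict_cutoff_and_self_exclusion(self):
        # residues at 0, 7.9 and 8.0 angstroms along x
        model = StructureModel(residues=(
            point_residue(1, (0, 0, 0)),
            point_residue(2, (7.9, 0, 0)),
            point_residue(3, (8.0, 0, 0)),
        ))
        counts = cc.cb_neighbor_counts(model)
        # 0 <-> 7.9 within; 0 <-> 8.0 NOT (strict); 7.9 <-> 8.0 within
        assert list(counts) == [1, 2, 1]

    def test_counts_invariant_to_atom_order(self):
        r1 = Residue(
            name="ALA", chain="A", seqid=1,
            atom_names=("CB", "CA"), elements=("C", "C"),
            coords=np.array([[0.0, 0, 0], [1.0, 0, 0]]),
        )
        r1_swapped = Residue(
            name="ALA", chain="A", seqid=1,
            atom_names=("CA", "CB"), elements=("C", "C"),
            coords=np.array([[1.0, 0, 0], [0.0, 0, 0]]),
        )
        other = point_residue(2, (5, 0, 0))
        c1 = cc.cb_neighbor_counts(StructureModel(residues=(r1, other)))
        c2 = cc.cb_neighbor_counts(StructureModel(residues=(r1_swapped, other)))
        assert list(c1) == list(c2)

    def test_glycine_virtual_cbeta(self):
        # glycine with backbone only gets a virtual CB ~1.5 A from CA
        gly = Residue(
            name="GLY", chain="A", seqid=1,
            atom_names=("N", "CA", "C"), elements=("N", "C", "C"),
            coords=np.array([[1.46, 0, 0], [0.0, 0, 0], [-0.55, 1.42, 0]]),
        )
        cb = cbeta_position(gly)
        assert 1.0 < np.linalg.norm(cb - gly.atom("CA")) < 2.2


class TestPairDistance:
    def test_self_distance_zero(self):
        model = StructureModel(residues=(point_residue(1, (1, 2, 3)),))
        assert cc.min_heavy_atom_distance(model, 0, 0) == 0.0

    def test_three_four_five(self):
        model = StructureModel(residues=(
            point_residue(1, (0, 0, 0)), point_residue(2, (3, 4, 0)),
        ))
        assert cc.min_heavy_atom_distance(model, 0, 1) == pytest.approx(5.0)

    def test_hydrogens_ignored(self):
        r1 = Residue(
            name="ALA", chain="A", seqid=1,
            atom_names=("CB", "HB"), elements=("C", "H"),
            coords=np.array([[0.0, 0, 0], [9.0, 0, 0]]),
        )
        r2 = Residue(
            name="ALA", chain="A", seqid=2,
            atom_names=("CB", "HB"), elements=("C", "H"),
            coords=np.array([[10.0, 0, 0], [0.5, 0, 0]]),
        )
        model = StructureModel(residues=(r1, r2))
        assert cc.min_heavy_atom_distance(model, 0, 1) == pytest.approx(10.0)

    def test_matches_brute_force_on_toy_models(self):
        rng = np.random.default_rng(3)
        residues = []
        for k in range(4):
            n_atoms = int(rng.integers(2, 6))
            coords = rng.normal(scale=5.0, size=(n_atoms, 3))
            residues.append(Residue(
                name="ALA", chain="A", seqid=k + 1,
                atom_names=tuple(f"C{t}" for t in range(n_atoms)),
                elements=("C",) * n_atoms,
                coords=coords,
            ))
        model = StructureModel(residues=tuple(residues))
        for i in range(4):
            for j in range(i + 1, 4):
                expected = min_distance_oracle(
                    residues[i].coords, residues[j].coords
                )
                assert cc.min_heavy_atom_distance(model, i, j) == pytest.approx(expected)

    def test_missing_residue(self):
        model = StructureModel(residues=(point_residue(1, (0, 0, 0)),))
        with pytest.raises(MissingDensityError):
            cc.min_heavy_atom_distance(model, 0, 5)


class TestInterface:
    def model(self):
        return StructureModel(residues=(
            point_residue(1, (0, 0, 0)), point_residue(2, (50, 0, 0)),
        ))

    def test_within_six_flagged(self):
        flags = cc.interface_positions(self.model(), np.array([[5.9, 0, 0]]))
        assert list(flags) == [True, False]

    def test_far_not_flagged(self):
        flags = cc.interface_positions(self.model(), np.array([[20.0, 0, 0]]))
        assert list(flags) == [False, False]

    def test_boundary_strict(self):
        flags = cc.interface_positions(self.model(), np.array([[6.0, 0, 0]]))
        assert list(flags) == [False, False]

    def test_empty_partner_rejected(self):
        with pytest.raises(ValueError):
            cc.interface_positions(self.model(), np.empty((0, 3)))

    def test_symmetric_when_swapped(self):
        rng = np.random.default_rng(5)
        a_coords = rng.normal(scale=4, size=(6, 3))
        b_coords = rng.normal(scale=4, size=(5, 3)) + np.array([4.0, 0, 0])
        mod_a = StructureModel(residues=tuple(
            point_residue(k + 1, c) for k, c in enumerate(a_coords)
        ))
        mod_b = StructureModel(residues=tuple(
            point_residue(k + 1, c) for k, c in enumerate(b_coords)
        ))
        flags_a = cc.interface_positions(mod_a, b_coords)
        flags_b = cc.interface_positions(mod_b, a_coords)
        assert flags_a.any() == flags_b.any()


class TestKabschRMSD:
    def test_identical_zero(self):
        p = np.random.default_rng(0).normal(size=(10, 3))
        assert kabsch_rmsd(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_zero(self):
        rng = np.random.default_rng(1)
        p = rng.normal(size=(12, 3))
        for seed in range(20):
            rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            q = (rot @ p.T).T + np.array([3.0, -2.0, 7.0])
            assert kabsch_rmsd(p, q) < 1e-6

    def test_reflection_not_allowed(self):
        # a mirrored set must NOT superpose to zero (proper rotations only)
        p = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        q = p.copy()
        q[:, 0] *= -1
        assert kabsch_rmsd(p, q) > 0.1

    def test_three_point_analytic(self):
        # p is an equilateral-ish triangle; q equals p with one vertex moved
        # along the normal: optimal superposition cannot remove the
        # displacement fully; cross-check against an independent oracle
        p = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0.0, 1.5, 0]])
        q = p.copy()
        q[2, 2] = 0.9
        rot, rssd = Rotation.align_vectors(
            (q - q.mean(0)), (p - p.mean(0)), return_sensitivity=False
        )[:2]
        expected = rssd / np.sqrt(len(p))
        assert kabsch_rmsd(p, q) == pytest.approx(expected, abs=1e-8)

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            p = rng.normal(size=(8, 3))
            q = rng.normal(size=(8, 3))
            _, rssd = Rotation.align_vectors(q - q.mean(0), p - p.mean(0))
            assert kabsch_rmsd(p, q) == pytest.approx(rssd / np.sqrt(8), abs=1e-8)


class TestStructuralVariation:
    def test_identical_ensemble_zero(self):
        model = cc.generate_structure(10, set(), seed=0)
        ens = cc.generate_ensemble(model, n_models=5, jitter_sd=0.0, seed=0)
        assert cc.structural_variation(ens, seed=1) == pytest.approx(0.0, abs=1e-12)

    def test_rigidly_transformed_ensemble_zero(self):
        model = cc.generate_structure(12, set(), seed=1)
        cas = model.ca_coords()
        ens = [model]
        rng = np.random.default_rng(2)
        for seed in range(4):
            rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            moved = []
            for r in model.residues:
                moved.append(Residue(
                    name=r.name, chain=r.chain, seqid=r.seqid,
                    atom_names=r.atom_names, elements=r.elements,
                    coords=(rot @ r.coords.T).T + np.array([1.0, 2.0, 3.0]),
                ))
            ens.append(StructureModel(residues=tuple(moved)))
        assert cc.structural_variation(ens, seed=3) < 1e-6

    def test_mismatched_sizes_rejected(self):
        m1 = cc.generate_structure(8, set(), seed=0)
        m2 = cc.generate_structure(9, set(), seed=0)
        with pytest.raises(ValueError):
            cc.structural_variation([m1, m2])

    def test_sampling_respects_sample_size(self):
        model = cc.generate_structure(8, set(), seed=3)
        ens = cc.generate_ensemble(model, n_models=15, jitter_sd=0.3, seed=4)
        v1 = cc.structural_variation(ens, sample=10, seed=5)
        v2 = cc.structural_variation(ens, sample=10, seed=5)
        assert v1 == v2  # deterministic for a fixed seed
        assert v1 > 0


class TestPdbRoundtrip:
    def test_write_read_roundtrip(self, tmp_path):
        model = cc.generate_structure(6, {(1, 4)}, seed=2)
        p = tmp_path / "toy.pdb"
        write_pdb(model, p)
        back = cc.read_structure(p)
        assert len(back) == 6
        d_orig = cc.min_heavy_atom_distance(model, 1, 4)
        d_back = cc.min_heavy_atom_distance(back, 1, 4)
        assert d_back == pytest.approx(d_orig, abs=1e-2)  # PDB precision

    def test_context_build(self):
        model = cc.generate_structure(10, set(), seed=5)
        ctx = build_context(model, partner_atoms=np.array([[0.0, 0, 0]]))
        assert len(ctx.burial) == 10
        assert ctx.interface is not None and len(ctx.interface) == 10
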