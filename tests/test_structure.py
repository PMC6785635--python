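"""Superposition, exposure and cavity-residue selection against brute-force oracles."""

import numpy as np
import pytest

import npfcavity as nc
from npfcavity.errors import MissingLigandError, PairingError, ProbeError
from conftest import brute_force_near_ligand


def horn_quaternion_rmsd(mobile, target):
    """Closed-form optimal-rotation RMSD (Horn's quaternion method) —
    independent of the SVD/Kabsch implementation path."""
    a = mobile - mobile.mean(axis=0)
    b = target - target.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    sq = ((a**2).sum() + (b**2).sum() - 2 * lam) / len(a)
    return float(np.sqrt(max(sq, 0.0)))


def _ca_only(coords):
    n = len(coords)
    return nc.StructureModel(
        res_id=np.arange(1, n + 1),
        res_name=np.array(["ALA"] * n),
        atom_name=np.array(["CA"] * n),
        element=np.array(["C"] * n),
        coord=np.asarray(coords, dtype=float),
        chain_id=np.array(["A"] * n),
        ligand_mask=np.zeros(n, dtype=bool),
    )


class TestSuperpose:
    def test_self_superposition_rmsd_zero(self, grid_structure):
        pairing = [(r, r) for r in grid_structure.residue_numbers()[:5]]
        _, rmsd = nc.superpose(grid_structure, grid_structure, pairing)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_translation_removed(self, grid_structure):
        moved = grid_structure.transformed(np.eye(3), np.array([5.0, 0.0, 0.0]))
        pairing = [(r, r) for r in grid_structure.residue_numbers()[:5]]
        _, rmsd = nc.superpose(moved, grid_structure, pairing)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_matches_quaternion_oracle_on_jittered_copy(self):
        rng = np.random.default_rng(7)
        target = _ca_only(rng.normal(size=(4, 3)) * 5)
        angle = np.deg2rad(40)
        rot = np.array([
            [np.cos(angle), -np.sin(angle), 0],
            [np.sin(angle), np.cos(angle), 0],
            [0, 0, 1],
        ])
        mobile = _ca_only(target.coord @ rot.T + rng.normal(scale=0.3, size=(4, 3)) + 2.0)
        pairing = [(i, i) for i in range(1, 5)]
        _, rmsd = nc.superpose(mobile, target, pairing)
        oracle = horn_quaternion_rmsd(mobile.coord, target.coord)
        assert rmsd == pytest.approx(oracle, abs=1e-6)

    def test_rmsd_invariant_under_joint_rigid_motion(self):
        rng = np.random.default_rng(3)
        a = _ca_only(rng.normal(size=(6, 3)) * 4)
        b = _ca_only(rng.normal(size=(6, 3)) * 4)
        pairing = [(i, i) for i in range(1, 7)]
        _, rmsd0 = nc.superpose(a, b, pairing)
        theta = 1.1
        rot = np.array([
            [1, 0, 0],
            [0, np.cos(theta), -np.sin(theta)],
            [0, np.sin(theta), np.cos(theta)],
        ])
        a2 = a.transformed(rot, np.array([1.0, -2.0, 3.0]))
        b2 = b.transformed(rot, np.array([1.0, -2.0, 3.0]))
        _, rmsd1 = nc.superpose(a2, b2, pairing)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-8)

    def test_too_few_pairs_rejected(self, grid_structure):
        with pytest.raises(PairingError):
            nc.superpose(grid_structure, grid_structure, [(1, 1), (2, 2)])

    def test_missing_ca_rejected(self, grid_structure):
        lig_res = int(grid_structure.res_id[grid_structure.ligand_mask][0])
        with pytest.raises(PairingError):
            nc.superpose(
                grid_structure, grid_structure, [(1, 1), (2, 2), (lig_res, 3)]
            )


class TestExposure:
    def test_isolated_residue_fully_exposed(self):
        # a whole free residue exceeds its per-type maximum area → clamped to 1
        n = 4
        s = nc.StructureModel(
            res_id=np.ones(n, dtype=int),
            res_name=np.array(["ALA"] * n),
            atom_name=np.array(["N", "CA", "C", "CB"]),
            element=np.array(["N", "C", "C", "C"]),
            coord=np.array([[0, 0, 0], [1.5, 0, 0], [2.2, 1.3, 0], [1.8, -1.0, 1.0]],
                           dtype=float),
            chain_id=np.array(["A"] * n),
            ligand_mask=np.zeros(n, dtype=bool),
        )
        assert nc.residue_exposure(s)[1] == pytest.approx(1.0)

    def test_buried_residue_near_zero(self):
        # Central atom enclosed by two dense spherical shells of carbons.
        pts = [np.zeros(3)]
        for radius in (4.0, 6.5):
            n = 350
            idx = np.arange(n) + 0.5
            phi = np.arccos(1 - 2 * idx / n)
            theta = np.pi * (1 + 5**0.5) * idx
            pts.extend(
                radius
                * np.column_stack(
                    [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
                )
            )
        coords = np.asarray(pts)
        n_atoms = len(coords)
        s = nc.StructureModel(
            res_id=np.concatenate([[1], np.full(n_atoms - 1, 2)]),
            res_name=np.array(["ALA"] * n_atoms),
            atom_name=np.array(["CA"] * n_atoms),
            element=np.array(["C"] * n_atoms),
            coord=coords,
            chain_id=np.array(["A"] * n_atoms),
            ligand_mask=np.zeros(n_atoms, dtype=bool),
        )
        assert nc.residue_exposure(s)[1] < 0.01

    def test_deterministic(self, grid_structure):
        assert nc.residue_exposure(grid_structure) == nc.residue_exposure(grid_structure)


class TestSelection:
    def test_boundary_791_included_811_excluded(self):
        inside = nc.generate_toy_structure(27, ligand_offset=7.9)
        outside = nc.generate_toy_structure(27, ligand_offset=8.1)
        assert nc.select_near_ligand(inside).residues == {1}
        assert nc.select_near_ligand(outside).residues == set()

    def test_far_ligand_selects_nothing(self):
        s = nc.generate_toy_structure(27, ligand_offset=20.0)
        assert nc.select_near_ligand(s).residues == set()

    def test_no_ligand_errors(self):
        s = nc.generate_toy_structure(8, ligand_offset=7.9)
        s = nc.StructureModel(
            res_id=s.res_id[s.protein_mask],
            res_name=s.res_name[s.protein_mask],
            atom_name=s.atom_name[s.protein_mask],
            element=s.element[s.protein_mask],
            coord=s.coord[s.protein_mask],
            chain_id=s.chain_id[s.protein_mask],
            ligand_mask=np.zeros(int(s.protein_mask.sum()), dtype=bool),
        )
        with pytest.raises(MissingLigandError):
            nc.select_near_ligand(s)

    @pytest.mark.parametrize("geometry,n", [("grid", 27), ("helix", 30), ("grid", 64)])
    def test_equals_brute_force_oracle(self, geometry, n):
        s = nc.generate_toy_structure(n, ligand_offset=6.0, geometry=geometry,
                                      ligand_anchor=n // 2)
        params = nc.SelectionParams()
        sel = nc.select_near_ligand(s, params)
        expo = nc.residue_exposure(s)
        oracle = brute_force_near_ligand(
            s, params.ligand_cutoff, expo, params.exposure_threshold
        )
        assert sel.residues == oracle

    def test_monotone_in_cutoff(self, grid_structure):
        small = nc.select_near_ligand(
            grid_structure, nc.SelectionParams(ligand_cutoff=6.0)
        ).residues
        large = nc.select_near_ligand(
            grid_structure, nc.SelectionParams(ligand_cutoff=14.0)
        ).residues
        assert small <= large

    def test_anti_monotone_in_exposure_threshold(self, grid_structure):
        lo = nc.select_near_ligand(
            grid_structure, nc.SelectionParams(exposure_threshold=0.0)
        ).residues
        hi = nc.select_near_ligand(
            grid_structure, nc.SelectionParams(exposure_threshold=0.9)
        ).residues
        assert hi <= lo

    def test_cavity_selection_boundary_and_union(self, grid_structure):
        ref1 = nc.CavityReference(reference_atoms=[(1, "CA")])
        ref2 = nc.CavityReference(reference_atoms=[(27, "CA")])
        both = nc.CavityReference(reference_atoms=[(1, "CA"), (27, "CA")])
        p = nc.SelectionParams(cavity_cutoff=12.0)
        s1 = nc.select_near_cavity(grid_structure, ref1, p).residues
        s2 = nc.select_near_cavity(grid_structure, ref2, p).residues
        s12 = nc.select_near_cavity(grid_structure, both, p).residues
        assert s12 == s1 | s2
        # 10 Å lattice neighbour inside the 12 Å cutoff, diagonal (14.1 Å) outside
        assert 2 in s1 and 5 not in s1

    def test_unresolvable_probe_errors(self, grid_structure):
        bad = nc.CavityReference(reference_atoms=[(999, "CA")])
        with pytest.raises(ProbeError, match="999"):
            nc.select_near_cavity(grid_structure, bad)


class TestMerge:
    def _pmap(self, n=60):
        seq = ("ACDEFGHIKLMNPQRSTVWY" * 3)[:n]
        aln = nc.Alignment(ids=["ref"], sequences=[seq])
        return nc.build_position_map(aln, "ref")

    def test_idempotent_union(self):
        sel = nc.ResidueSelection(structure_id="s1", residues={1, 2, 3})
        sel2 = nc.ResidueSelection(structure_id="s2", residues={1, 2, 3})
        pm = self._pmap()
        merged = nc.merge_selections([sel, sel2], {"s1": pm, "s2": pm})
        assert merged.columns == [1, 2, 3]

    def test_disjoint_union(self):
        a = nc.ResidueSelection(structure_id="s1", residues={1, 2})
        b = nc.ResidueSelection(structure_id="s2", residues={3})
        pm = self._pmap()
        assert nc.merge_selections([a, b], {"s1": pm, "s2": pm}).columns == [1, 2, 3]

    def test_inclusion_exclusion_gives_51_positions(self):
        # 30 and 35 residues sharing 14 → union of 51, as for a two-conformation
        # cavity selection merged in alignment coordinates.
        a = nc.ResidueSelection(structure_id="s1", residues=set(range(1, 31)))
        b = nc.ResidueSelection(structure_id="s2", residues=set(range(17, 52)))
        pm = self._pmap()
        merged = nc.merge_selections([a, b], {"s1": pm, "s2": pm})
        assert len(merged.columns) == 51

    def test_unmapped_residue_reported_not_dropped(self):
        pm = self._pmap(n=10)
        sel = nc.ResidueSelection(structure_id="s1", residues={5, 99})
        merged = nc.merge_selections([sel], {"s1": pm})
        assert merged.columns == [5]
        assert ("s1", 99) in merged.unmapped
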