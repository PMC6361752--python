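"""The five model descriptors, conformer generation and matrix plumbing."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from zfqsar.descriptors import (
    DESCRIPTOR_NAMES,
    DescriptorMatrix,
    PROBE_RADIUS,
    atom_partial_charges,
    build_descriptor_matrix,
    compute_descriptor_vector,
    count_aliphatic_single_bonds,
    count_aromatic_bonds,
    embed_and_minimize,
    hbd_count,
    jurs_wpsa1,
    mol_from_smiles,
    prune_descriptors,
    qed_mw,
    qed_mw_from_weight,
    read_structures,
    shrake_rupley_sasa,
)
from zfqsar.errors import EmptyMatrixError, JoinError, StructureError


def mol(smiles):
    return mol_from_smiles(smiles)


class TestGraphDescriptors:
    @pytest.mark.parametrize(
        "smiles, expected",
        [("CCO", 1), ("c1ccccc1", 0), ("Nc1ccc(O)cc1", 2), ("NCC(=O)O", 2)],
    )
    def test_hbd_counts_donor_atoms_once(self, smiles, expected):
        assert hbd_count(mol(smiles)) == expected

    @pytest.mark.parametrize(
        "smiles, expected",
        [("CC", 1), ("c1ccccc1", 0), ("Cc1ccccc1", 1), ("CCOC", 3)],
    )
    def test_aliphatic_single_bonds_heavy_atoms_only(self, smiles, expected):
        assert count_aliphatic_single_bonds(mol(smiles)) == expected

    @pytest.mark.parametrize(
        "smiles, expected",
        [("c1ccccc1", 6), ("CC", 0), ("c1ccc2ccccc2c1", 11)],
    )
    def test_aromatic_bond_counts(self, smiles, expected):
        assert count_aromatic_bonds(mol(smiles)) == expected

    def test_unparsable_structure_raises(self):
        with pytest.raises(StructureError):
            mol_from_smiles("not-a-smiles(((")

    def test_permutation_invariance_of_graph_counts(self, rng):
        m = mol("CC(=O)Nc1ccc(O)cc1")  # paracetamol
        perm = [int(i) for i in rng.permutation(m.GetNumAtoms())]
        shuffled = Chem.RenumberAtoms(m, perm)
        for fn in (hbd_count, count_aliphatic_single_bonds, count_aromatic_bonds,
                   qed_mw):
            assert fn(shuffled) == fn(m)


class TestQEDMolecularWeightDesirability:
    def test_normalized_supremum_is_one(self):
        grid = np.linspace(10.0, 1500.0, 20000)
        values = np.array([qed_mw_from_weight(w) for w in grid])
        assert values.max() == pytest.approx(1.0, abs=1e-4)
        assert values.max() <= 1.0 + 1e-12

    def test_tail_declines_beyond_drug_like_weights(self):
        assert qed_mw_from_weight(1000.0) < qed_mw_from_weight(300.0)

    def test_benzene_matches_independent_ads_evaluation(self):
        # asymmetric double sigmoid with the published parameters,
        # re-evaluated by hand at MW(benzene) = 78.114
        a, b, c, d, e, f, dmax = (
            2.817065973, 392.5754953, 290.7489764, 2.419764353,
            49.22325677, 65.37051707, 104.9805561,
        )
        x = 78.114
        expected = (
            a
            + b
            / (1 + np.exp(-(x - c + d / 2) / e))
            * (1 - 1 / (1 + np.exp(-(x - c - d / 2) / f)))
        ) / dmax
        assert qed_mw(mol("c1ccccc1")) == pytest.approx(expected, rel=1e-6)


class TestSasaAndWPSA1:
    def test_isolated_sphere_area_is_exact(self):
        areas = shrake_rupley_sasa(np.zeros((1, 3)), [1.7])
        assert areas[0] == pytest.approx(4 * np.pi * (1.7 + PROBE_RADIUS) ** 2)

    def test_buried_atom_has_zero_area(self):
        # small sphere at the centre of a large engulfing one
        coords = np.zeros((2, 3))
        areas = shrake_rupley_sasa(coords, [0.5, 3.0])
        assert areas[0] == 0.0

    def test_scaling_coordinates_radii_and_probe_scales_areas_quadratically(
        self, rng
    ):
        coords = rng.uniform(-2, 2, size=(5, 3))
        radii = rng.uniform(1.2, 1.9, size=5)
        c = 1.7
        base = shrake_rupley_sasa(coords, radii, probe_radius=1.4)
        scaled = shrake_rupley_sasa(c * coords, c * radii, probe_radius=c * 1.4)
        np.testing.assert_allclose(scaled, c**2 * base, rtol=1e-12)

    def test_monte_carlo_sphere_oracle_on_methane(self, rng):
        """Independent random-direction surface integration agrees with the
        lattice-based implementation on a real conformer."""
        m3 = embed_and_minimize(mol("C"), seed=11)
        coords = m3.GetConformer().GetPositions()
        table = Chem.GetPeriodicTable()
        radii = np.array([table.GetRvdw(a.GetAtomicNum()) for a in m3.GetAtoms()])
        areas = shrake_rupley_sasa(coords, radii)
        expanded = radii + PROBE_RADIUS
        n_mc = 40000
        mc = np.empty(len(radii))
        for i in range(len(radii)):
            pts = rng.standard_normal((n_mc, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            pts = coords[i] + expanded[i] * pts
            free = np.ones(n_mc, dtype=bool)
            for j in range(len(radii)):
                if j != i:
                    free &= np.linalg.norm(pts - coords[j], axis=1) >= expanded[j]
            mc[i] = 4 * np.pi * expanded[i] ** 2 * free.mean()
        np.testing.assert_allclose(areas, mc, rtol=0.03)

    def test_against_freesasa_total_area(self):
        """Cross-check the total accessible surface against the FreeSASA
        library (Shrake-Rupley, identical radii) on a drug-sized molecule."""
        rdFreeSASA = pytest.importorskip("rdkit.Chem.rdFreeSASA")
        m3 = embed_and_minimize(mol("CC(=O)Nc1ccc(O)cc1"), seed=3)
        coords = m3.GetConformer().GetPositions()
        table = Chem.GetPeriodicTable()
        radii = [table.GetRvdw(a.GetAtomicNum()) for a in m3.GetAtoms()]
        mine = shrake_rupley_sasa(coords, radii).sum()
        opts = rdFreeSASA.SASAOpts(
            rdFreeSASA.SASAAlgorithm.ShrakeRupley,
            rdFreeSASA.SASAClassifier.Protor,
            PROBE_RADIUS,
        )
        theirs = rdFreeSASA.CalcSASA(m3, radii, confIdx=-1, opts=opts)
        assert mine == pytest.approx(theirs, rel=0.02)

    def test_wpsa1_methane_decomposition(self):
        """In methane the carbon is the sole negative atom, so PPSA-1 is
        the summed hydrogen surface and WPSA-1 = PPSA-1 * TMSA / 100."""
        m3 = embed_and_minimize(mol("C"), seed=5)
        coords = m3.GetConformer().GetPositions()
        table = Chem.GetPeriodicTable()
        radii = [table.GetRvdw(a.GetAtomicNum()) for a in m3.GetAtoms()]
        areas = shrake_rupley_sasa(coords, radii)
        charges = atom_partial_charges(m3)
        assert charges[0] < 0 and (charges[1:] > 0).all()
        expected = areas[1:].sum() * areas.sum() / 100.0
        assert jurs_wpsa1(m3) == pytest.approx(expected, rel=1e-12)

    def test_wpsa1_requires_coordinates(self):
        with pytest.raises(Exception, match="3D"):
            jurs_wpsa1(mol("CCO"))

    def test_wpsa1_invariant_under_atom_renumbering(self, rng):
        m3 = embed_and_minimize(mol("CCO"), seed=9)
        perm = [int(i) for i in rng.permutation(m3.GetNumAtoms())]
        shuffled = Chem.RenumberAtoms(m3, perm)
        assert jurs_wpsa1(shuffled) == pytest.approx(jurs_wpsa1(m3), rel=1e-12)


class TestEmbedAndMinimize:
    def test_deterministic_for_fixed_seed(self):
        m1 = embed_and_minimize(mol("CC(=O)Nc1ccc(O)cc1"), seed=42)
        m2 = embed_and_minimize(mol("CC(=O)Nc1ccc(O)cc1"), seed=42)
        np.testing.assert_array_equal(
            m1.GetConformer().GetPositions(), m2.GetConformer().GetPositions()
        )

    def test_heavy_atom_count_preserved(self):
        m = mol("CC(=O)Nc1ccc(O)cc1")
        m3 = embed_and_minimize(m, seed=0)
        heavy = sum(1 for a in m3.GetAtoms() if a.GetAtomicNum() > 1)
        assert heavy == m.GetNumAtoms()

    def test_minimization_does_not_raise_energy(self):
        m3 = embed_and_minimize(mol("CCCCO"), seed=1)
        assert m3.GetDoubleProp("E_minimized") <= m3.GetDoubleProp("E_initial")


class TestMatrixAssembly:
    def test_matrix_shape_and_column_order(self):
        structures = [("benzene", mol("c1ccccc1")), ("ethanol", mol("CCO"))]
        matrix = build_descriptor_matrix(structures, seed=0)
        assert matrix.compound_ids == ["benzene", "ethanol"]
        assert tuple(matrix.descriptor_names) == DESCRIPTOR_NAMES
        assert matrix.values.shape == (2, 5)

    def test_rows_equal_single_molecule_operations(self):
        structures = [("benzene", mol("c1ccccc1")), ("ethanol", mol("CCO"))]
        matrix = build_descriptor_matrix(structures, seed=7)
        single = compute_descriptor_vector(mol("c1ccccc1"), seed=7)
        np.testing.assert_allclose(matrix.values[0], single.as_array())

    def test_extra_columns_appended(self):
        structures = [("a", mol("CCO")), ("b", mol("CCC"))]
        extra = DescriptorMatrix(
            compound_ids=["b", "a"],
            descriptor_names=["e1", "e2", "e3"],
            values=np.arange(6.0).reshape(2, 3),
        )
        matrix = build_descriptor_matrix(structures, seed=0, extra=extra)
        assert matrix.values.shape == (2, 8)
        assert matrix.descriptor_names[-3:] == ["e1", "e2", "e3"]
        # extra rows realigned to structure order
        np.testing.assert_array_equal(matrix.values[0, 5:], [3.0, 4.0, 5.0])

    def test_name_mismatch_lists_offenders(self):
        structures = [("a", mol("CCO"))]
        extra = DescriptorMatrix(
            compound_ids=["zz"], descriptor_names=["e1"], values=[[1.0]]
        )
        with pytest.raises(JoinError, match="zz"):
            build_descriptor_matrix(structures, extra=extra)

    def test_smiles_file_reader(self, tmp_path):
        path = tmp_path / "mols.smi"
        path.write_text("benzene\tc1ccccc1\nethanol\tCCO\n")
        structures = read_structures(path)
        assert [name for name, _ in structures] == ["benzene", "ethanol"]


class TestPruning:
    def make(self, values, names=None):
        values = np.asarray(values, float)
        return DescriptorMatrix(
            compound_ids=[f"c{i}" for i in range(values.shape[0])],
            descriptor_names=names or [f"d{j}" for j in range(values.shape[1])],
            values=values,
        )

    def test_constant_column_dropped(self, rng):
        matrix = self.make(
            np.column_stack([np.ones(10), rng.standard_normal(10)])
        )
        pruned = prune_descriptors(matrix, variance_floor=1e-8)
        assert pruned.descriptor_names == ["d1"]

    def test_dominated_column_dropped(self, rng):
        col = np.zeros(20)
        col[0] = 1.0  # 19/20 identical values
        matrix = self.make(np.column_stack([col, rng.standard_normal(20)]))
        pruned = prune_descriptors(matrix, dominance_ceiling=0.9)
        assert pruned.descriptor_names == ["d1"]

    def test_non_finite_column_dropped(self, rng):
        col = rng.standard_normal(10)
        col[3] = np.nan
        matrix = self.make(np.column_stack([col, rng.standard_normal(10)]))
        assert prune_descriptors(matrix).descriptor_names == ["d1"]

    def test_well_scaled_columns_retained_and_idempotent(self, rng):
        matrix = self.make(rng.standard_normal((15, 4)))
        once = prune_descriptors(matrix)
        twice = prune_descriptors(once)
        assert once.descriptor_names == matrix.descriptor_names
        np.testing.assert_array_equal(once.values, twice.values)

    def test_all_columns_dropped_raises(self):
        matrix = self.make(np.ones((5, 2)))
        with pytest.raises(EmptyMatrixError):
            prune_descriptors(matrix)
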