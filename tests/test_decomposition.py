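import math

import pytest
from rdkit import Chem

from mcspace.decomposition import (
    GapProfile,
    NoMacrocycleError,
    attachment_positions,
    classify_atoms,
    compute_gaps,
    decompose,
    detect_multifusion,
    find_mc_ring,
    restricted_fraction,
)
from mcspace.synthetic import (
    GeneratorSpec,
    SubstituentSpec,
    generate_macrocycle,
    generate_multifusion_example,
)


class TestFindMCRing:
    def test_cyclododecane_unique_cycle(self, cyclododecane):
        ring = find_mc_ring(cyclododecane, 11)
        assert len(ring) == 12
        assert set(ring) == set(range(12))

    def test_too_small_raises(self):
        mol = Chem.MolFromSmiles("C1CCCC1")
        with pytest.raises(NoMacrocycleError):
            find_mc_ring(mol, 11)

    def test_acyclic_raises(self):
        with pytest.raises(NoMacrocycleError):
            find_mc_ring(Chem.MolFromSmiles("CCCCCCCCCCCCC"), 11)

    def test_fused_benzo_returns_12_not_envelope(self, fused_benzo_12):
        """Ortho-fused benzene: the 12-cycle must win over both the
        6-cycle and the 16-atom envelope detouring around the benzene."""
        ring = find_mc_ring(fused_benzo_12, 11)
        assert len(ring) == 12
        # the ring holds the 10 sp3 carbons plus the two fusion aromatics
        sp3 = {a.GetIdx() for a in fused_benzo_12.GetAtoms()
               if a.GetHybridization() == Chem.HybridizationType.SP3}
        aromatic_in_ring = [i for i in ring
                            if fused_benzo_12.GetAtomWithIdx(i).GetIsAromatic()]
        assert sp3 <= set(ring)
        assert len(aromatic_in_ring) == 2

    def test_deterministic(self, fused_benzo_12):
        assert find_mc_ring(fused_benzo_12, 11) == find_mc_ring(fused_benzo_12, 11)


class TestClassifyAtoms:
    def test_hydroxyl_is_peripheral(self):
        mol = Chem.MolFromSmiles("OC1CCCCCCCCCCC1")
        d = decompose(mol)
        assert len(d.peripheral_atoms) == 1
        assert list(d.peripheral_atoms.values()) == ["O"]
        assert d.substituents == []

    def test_lactone_carbonyl_o_is_peripheral_ring_o_is_ring(self):
        mol = Chem.MolFromSmiles("O=C1CCCCCCCCCCO1")  # 12-ring lactone
        d = decompose(mol)
        assert len(d.ring_atoms) == 12
        ring_syms = sorted(mol.GetAtomWithIdx(i).GetSymbol() for i in d.ring_atoms)
        assert ring_syms.count("O") == 1
        assert list(d.peripheral_atoms.values()) == ["O"]

    def test_ethyl_is_substituent(self):
        mol = Chem.MolFromSmiles("CCC1CCCCCCCCCCC1")
        d = decompose(mol)
        assert len(d.peripheral_atoms) == 0
        assert len(d.substituents) == 1
        assert d.substituents[0].size == 2
        assert not d.substituents[0].fused
        assert not d.substituents[0].spiro

    def test_partition_completeness(self, small_library):
        for g in small_library:
            d = decompose(g.mol)
            n_total = (len(d.ring_atoms) + len(d.peripheral_atoms)
                       + len(d.substituent_atoms))
            assert n_total == g.mol.GetNumHeavyAtoms()

    def test_spiro_flag(self):
        gm = generate_macrocycle(GeneratorSpec(
            ring_size=12, substituent_plan=(SubstituentSpec(0, 4, "spiro"),)))
        d = decompose(gm.mol)
        assert len(d.substituents) == 1
        assert d.substituents[0].spiro
        assert not d.substituents[0].fused

    def test_fused_flag(self):
        gm = generate_macrocycle(GeneratorSpec(
            ring_size=12, substituent_plan=(SubstituentSpec(0, 4, "fused"),)))
        d = decompose(gm.mol)
        assert len(d.substituents) == 1
        assert d.substituents[0].fused
        assert tuple(sorted(d.substituents[0].attachment_ring_atoms)) == (0, 1)


class TestMultifusion:
    def test_perifused_true(self):
        mol = generate_multifusion_example()
        d = decompose(mol)
        assert d.multifusion is True

    def test_single_fused_benzene_false(self, fused_benzo_12):
        d = decompose(fused_benzo_12)
        assert d.multifusion is False

    def test_spiro_is_not_fusion(self):
        gm = generate_macrocycle(GeneratorSpec(
            ring_size=12, substituent_plan=(SubstituentSpec(0, 5, "spiro"),)))
        assert decompose(gm.mol).multifusion is False


class TestComputeGaps:
    def make_decomp(self, n, positions, sizes=None):
        subs = tuple(SubstituentSpec(p, 2, "alkyl") for p in positions)
        gm = generate_macrocycle(GeneratorSpec(ring_size=n, substituent_plan=subs))
        return decompose(gm.mol)

    def test_hand_counted_example(self):
        """N=14, attachments at ring positions {1,4,6,11}: walking the
        cycle gives gaps {2,1,4,3}; 2+1+4+3+4 = 14 checks conservation."""
        d = self.make_decomp(14, [1, 4, 6, 11])
        prof = compute_gaps(d)
        assert sorted(prof.gaps) == [1, 2, 3, 4]
        assert prof.max_gap == 4
        assert prof.min_gap == 1
        assert prof.mean_gap == pytest.approx(2.5)
        assert sum(prof.gaps) + prof.n_attachment_points == 14

    def test_single_attachment(self):
        d = self.make_decomp(12, [0])
        prof = compute_gaps(d)
        assert prof.gaps == [11]

    def test_no_attachment_convention(self, cyclododecane):
        prof = compute_gaps(decompose(cyclododecane))
        assert (prof.max_gap, prof.min_gap, prof.mean_gap, prof.stdev_gap) == (12, 12, 12, 0)

    def test_population_stdev(self):
        d = self.make_decomp(14, [1, 4, 6, 11])
        prof = compute_gaps(d)
        mu = 2.5
        expected = math.sqrt(sum((g - mu) ** 2 for g in [2, 1, 4, 3]) / 4)
        assert prof.stdev_gap == pytest.approx(expected)

    def test_gap_conservation_on_library(self, small_library):
        for g in small_library:
            d = decompose(g.mol)
            prof = compute_gaps(d)
            if prof.n_attachment_points >= 1:
                assert sum(prof.gaps) + prof.n_attachment_points == d.N

    def test_ring_atom_with_peripheral_and_substituent_counts_once(self):
        gm = generate_macrocycle(GeneratorSpec(
            ring_size=12,
            substituent_plan=(SubstituentSpec(0, 2, "alkyl"),
                              SubstituentSpec(4, 2, "alkyl"))))
        d = decompose(gm.mol)
        assert len(attachment_positions(d)) == 2


class TestRestrictedFraction:
    def test_cyclododecane_zero(self, cyclododecane):
        d = decompose(cyclododecane)
        assert restricted_fraction(d, cyclododecane) == 0.0

    def test_cyclododecene_single_pi(self):
        mol = Chem.MolFromSmiles("C1CCCCCCCCCC=C1")
        d = decompose(mol)
        assert restricted_fraction(d, mol) == pytest.approx(1 / 12)

    def test_hexaglycine_amides(self, hexaglycine):
        d = decompose(hexaglycine)
        assert d.N == 18
        assert restricted_fraction(d, hexaglycine) == pytest.approx(6 / 18)

    def test_fused_bond_counts(self):
        gm = generate_macrocycle(GeneratorSpec(
            ring_size=12, substituent_plan=(SubstituentSpec(0, 4, "fused"),)))
        d = decompose(gm.mol)
        assert restricted_fraction(d, gm.mol) == pytest.approx(1 / 12)

    def test_bounds_on_library(self, small_library):
        for g in small_library:
            d = decompose(g.mol)
            assert 0.0 <= restricted_fraction(d, g.mol) <= 1.0


class TestGroundTruthOracle:
    """classify_atoms must reproduce construction labels exactly."""

    def test_decomposition_matches_construction(self, small_library):
        for g in small_library:
            d = decompose(g.mol)
            gt = g.decomposition
            assert set(d.ring_atoms) == set(gt.ring_atoms)
            assert d.peripheral_atoms == gt.peripheral_atoms
            got = {(s.atoms, tuple(sorted(s.attachment_ring_atoms)), s.fused, s.spiro)
                   for s in d.substituents}
            exp = {(s.atoms, tuple(sorted(s.attachment_ring_atoms)), s.fused, s.spiro)
                   for s in gt.substituents}
            assert got == exp
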