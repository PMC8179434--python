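"""Registry of the 90 molecular descriptors (MolDs) computed per compound.

The registry mixes three origins: 32 well-known descriptors of general
druglikeness (MW, clogP, tPSA, HBD/HBA, rotatable bonds, ...), 12
descriptors embodying earlier macrocycle design guidelines, and 46
macrocycle-specific descriptors built on the ring / peripheral /
substituent decomposition (counts and elemental composition per positional
class, substituent gap statistics raw and normalized by ring size N, ring
rigidity, spiro/fusion topology, peptide character).

Zero-denominator ratios evaluate to 0 and are flagged as exceptions on the
vector rather than propagating NaN — a constant, flagged column must not
poison downstream PCA.

Conventions that are assumptions rather than published formulas (peptide
character index = 3 x ring-amides / N clipped to [0, 1]; ring complexity =
fraction of ring atoms bearing any decoration) are marked in the spec
table and can be overridden by registering a replacement callable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Callable

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, rdMolDescriptors

from mcspace.decomposition import (
    MCDecomposition,
    GapProfile,
    attachment_positions,
    compute_gaps,
    decompose,
    restricted_fraction,
    ring_amide_bond_count,
    ring_bond_restrictions,
    _attachment_positions_with_peripheral,
    _mol_graph,
)

HALOGENS = {"F", "Cl", "Br", "I"}

CATEGORIES = ("classic", "size-composition", "peripheral", "substituent",
              "gap", "rigidity", "normalized", "other")
ORIGINS = ("classic", "guideline", "novel")


@dataclass(frozen=True)
class DescriptorSpec:
    mold_id: int
    name: str
    category: str
    origin: str                     # classic | guideline | novel
    scaling_kind: str = "discrete"  # continuous only for MW, tPSA, clogP
    bounded01: bool = False         # true fraction, must lie in [0, 1]
    reconstructed: bool = False     # formula assumed, not published
    func: Callable[["DescriptorContext"], float] = field(
        default=lambda ctx: math.nan, compare=False, repr=False)

    @property
    def mc_specific(self) -> bool:
        return self.origin == "novel"

    @property
    def column(self) -> str:
        safe = "".join(c if c.isalnum() else "_" for c in self.name)
        return f"mold_{self.mold_id}_{safe}"


@dataclass
class DescriptorVector:
    compound_id: str
    values: dict[int, float]
    exceptions: list[tuple[int, str]] = field(default_factory=list)
    incomplete: bool = False

    def __getitem__(self, mold_id: int) -> float:
        return self.values[mold_id]


class ZeroDenominator(Exception):
    """Internal signal: ratio with empty denominator -> 0, flagged."""


class DescriptorContext:
    """Per-compound cache shared by all descriptor callables."""

    def __init__(self, mol: Chem.Mol, decomp: MCDecomposition):
        self.mol = mol
        self.decomp = decomp

    # ---- atom-class partitions -------------------------------------------
    @cached_property
    def ring_atoms(self) -> list[Chem.Atom]:
        return [self.mol.GetAtomWithIdx(i) for i in self.decomp.ring_atoms]

    @cached_property
    def peripheral_atoms(self) -> list[Chem.Atom]:
        return [self.mol.GetAtomWithIdx(i) for i in self.decomp.peripheral_atoms]

    @cached_property
    def substituent_atoms(self) -> list[Chem.Atom]:
        return [self.mol.GetAtomWithIdx(i) for i in sorted(self.decomp.substituent_atoms)]

    def count(self, atoms: list[Chem.Atom], symbol: str) -> int:
        return sum(1 for a in atoms if a.GetSymbol() == symbol)

    # ---- gap statistics ---------------------------------------------------
    @cached_property
    def gaps(self) -> GapProfile:
        return compute_gaps(self.decomp)

    # ---- rigidity ---------------------------------------------------------
    @cached_property
    def restricted(self) -> float:
        return restricted_fraction(self.decomp, self.mol)

    @cached_property
    def ring_amides(self) -> int:
        return ring_amide_bond_count(self.decomp, self.mol)

    @cached_property
    def chiral_centers(self) -> int:
        return len(Chem.FindMolChiralCenters(
            self.mol, includeUnassigned=True, useLegacyImplementation=False))

    @cached_property
    def peripheral_methyls(self) -> int:
        return sum(
            1 for a in self.peripheral_atoms
            if a.GetSymbol() == "C" and a.GetTotalNumHs() == 3)


def _ratio(num: float, den: float) -> float:
    if den == 0:
        raise ZeroDenominator
    return num / den


# --------------------------------------------------------------------------
# descriptor callables
# --------------------------------------------------------------------------

def _mw(c): return Descriptors.MolWt(c.mol)
def _hbd(c): return rdMolDescriptors.CalcNumHBD(c.mol)
def _hba(c): return rdMolDescriptors.CalcNumHBA(c.mol)
def _nrb(c): return rdMolDescriptors.CalcNumRotatableBonds(c.mol)
def _heavy(c): return c.mol.GetNumHeavyAtoms()
def _clogp(c): return Crippen.MolLogP(c.mol)
def _nrings(c): return rdMolDescriptors.CalcNumRings(c.mol)
def _tpsa(c): return Descriptors.TPSA(c.mol)
def _narom_rings(c): return rdMolDescriptors.CalcNumAromaticRings(c.mol)
def _fsp3(c): return rdMolDescriptors.CalcFractionCSP3(c.mol)
def _chiral(c): return c.chiral_centers


def _elem_count(symbol):
    def f(c):
        return sum(1 for a in c.mol.GetAtoms() if a.GetSymbol() == symbol)
    return f


def _halogen_count(c):
    return sum(1 for a in c.mol.GetAtoms() if a.GetSymbol() in HALOGENS)


_AMIDE = Chem.MolFromSmarts("[CX3](=O)[NX3]")


def _amide_count(c):
    return len(c.mol.GetSubstructMatches(_AMIDE))


def _aromatic_atoms(c):
    return sum(1 for a in c.mol.GetAtoms() if a.GetIsAromatic())


def _carbons_hyb(hyb):
    def f(c):
        return sum(1 for a in c.mol.GetAtoms()
                   if a.GetSymbol() == "C" and a.GetHybridization() == hyb)
    return f


def _heteroatoms(c):
    return sum(1 for a in c.mol.GetAtoms() if a.GetSymbol() not in ("C", "H"))


def _abs_charge(c):
    return sum(abs(a.GetFormalCharge()) for a in c.mol.GetAtoms())


# guideline block -----------------------------------------------------------

def _chiral_per_ha(c): return _ratio(c.chiral_centers, c.mol.GetNumHeavyAtoms())


def _ring_het_per_n(c):
    het = sum(1 for a in c.ring_atoms if a.GetSymbol() not in ("C", "H"))
    return het / c.decomp.N


def _periph_ha(c): return len(c.peripheral_atoms)
def _periph_methyl(c): return c.peripheral_methyls
def _periph_o(c): return c.count(c.peripheral_atoms, "O")
def _periph_c(c): return c.count(c.peripheral_atoms, "C")
def _periph_n(c): return c.count(c.peripheral_atoms, "N")
def _sub_count(c): return len(c.decomp.substituents)
def _ring_size(c): return c.decomp.N
def _periph_per_n(c): return len(c.peripheral_atoms) / c.decomp.N
def _sub_ha_per_ha(c): return len(c.substituent_atoms) / c.mol.GetNumHeavyAtoms()
def _ring_ha_per_ha(c): return c.decomp.N / c.mol.GetNumHeavyAtoms()


# novel block ---------------------------------------------------------------

def _periph_ratio_no(c):
    return (c.count(c.peripheral_atoms, "N") + 1) / (c.count(c.peripheral_atoms, "O") + 1)


def _spiro_rings(c):
    return sum(1 for s in c.decomp.substituents if s.spiro)


def _periph_frac(symbol):
    def f(c):
        return _ratio(c.count(c.peripheral_atoms, symbol), len(c.peripheral_atoms))
    return f


def _periph_halogens(c):
    return sum(1 for a in c.peripheral_atoms if a.GetSymbol() in HALOGENS)


def _periph_halogen_frac(c):
    return _ratio(_periph_halogens(c), len(c.peripheral_atoms))


def _ring_elem(symbol):
    def f(c):
        return c.count(c.ring_atoms, symbol)
    return f


def _ring_het_count(c):
    return sum(1 for a in c.ring_atoms if a.GetSymbol() not in ("C", "H"))


def _ring_pi_bonds(c):
    decomp, mol = c.decomp, c.mol
    ring, N = decomp.ring_atoms, decomp.N
    n = 0
    for i in range(N):
        b = mol.GetBondBetweenAtoms(ring[i], ring[(i + 1) % N])
        if b.GetIsAromatic() or b.GetBondTypeAsDouble() > 1.0:
            n += 1
    return n


def _ring_amide_count(c): return c.ring_amides


def _ring_sp3c_frac(c):
    ring_c = [a for a in c.ring_atoms if a.GetSymbol() == "C"]
    sp3 = sum(1 for a in ring_c if a.GetHybridization() == Chem.HybridizationType.SP3)
    return _ratio(sp3, len(ring_c))


def _ring_aromatic_frac(c):
    return sum(1 for a in c.ring_atoms if a.GetIsAromatic()) / c.decomp.N


def _sub_ha(c): return len(c.substituent_atoms)
def _sub_c(c): return c.count(c.substituent_atoms, "C")


def _sub_fsp3(c):
    carbons = [a for a in c.substituent_atoms if a.GetSymbol() == "C"]
    sp3 = sum(1 for a in carbons if a.GetHybridization() == Chem.HybridizationType.SP3)
    return _ratio(sp3, len(carbons))


def _sub_o(c): return c.count(c.substituent_atoms, "O")
def _sub_n(c): return c.count(c.substituent_atoms, "N")
def _sub_o_frac(c): return _ratio(c.count(c.substituent_atoms, "O"), len(c.substituent_atoms))
def _sub_n_frac(c): return _ratio(c.count(c.substituent_atoms, "N"), len(c.substituent_atoms))


def _sub_sizes(c):
    return [s.size for s in c.decomp.substituents]


def _max_sub(c):
    sizes = _sub_sizes(c)
    return max(sizes) if sizes else 0.0


def _min_sub(c):
    sizes = _sub_sizes(c)
    return min(sizes) if sizes else 0.0


def _mean_sub(c):
    sizes = _sub_sizes(c)
    return sum(sizes) / len(sizes) if sizes else 0.0


def _stdev_sub(c):
    sizes = _sub_sizes(c)
    if not sizes:
        return 0.0
    mu = sum(sizes) / len(sizes)
    return math.sqrt(sum((s - mu) ** 2 for s in sizes) / len(sizes))


def _gap_max(c): return c.gaps.max_gap
def _gap_min(c): return c.gaps.min_gap
def _gap_mean(c): return c.gaps.mean_gap
def _gap_stdev(c): return c.gaps.stdev_gap
def _gap_max_n(c): return c.gaps.max_gap / c.decomp.N
def _gap_min_n(c): return c.gaps.min_gap / c.decomp.N
def _gap_mean_n(c): return c.gaps.mean_gap / c.decomp.N
def _gap_stdev_n(c): return c.gaps.stdev_gap / c.decomp.N
def _attach_count(c): return len(attachment_positions(c.decomp))
def _attach_per_n(c): return len(attachment_positions(c.decomp)) / c.decomp.N
def _restricted(c): return c.restricted


def _ring_fusion_bonds(c):
    flags = ring_bond_restrictions(c.decomp, c.mol)
    # recompute only the fusion component: shared-with-another-ring bonds
    import networkx as nx
    ring, N = c.decomp.ring_atoms, c.decomp.N
    g = _mol_graph(c.mol)
    for i in range(N):
        g.remove_edge(ring[i], ring[(i + 1) % N])
    comp = {n: ci for ci, cc in enumerate(nx.connected_components(g)) for n in cc}
    return sum(1 for i in range(N) if comp[ring[i]] == comp[ring[(i + 1) % N]])


def _fused_sub_count(c):
    return sum(1 for s in c.decomp.substituents if s.fused)


def _ring_complexity(c):
    """Fraction of ring atoms bearing any peripheral group or substituent
    (substituent atoms and peripheral groups treated as equivalent)."""
    positions = _attachment_positions_with_peripheral(c.decomp, c.mol)
    return len(positions) / c.decomp.N


def _sub_aromatic_frac(c):
    return _ratio(sum(1 for a in c.substituent_atoms if a.GetIsAromatic()),
                  len(c.substituent_atoms))


def _sub_ring_count(c):
    mc = set(c.decomp.ring_atoms)
    sub = c.decomp.substituent_atoms
    n = 0
    for atom_ring in c.mol.GetRingInfo().AtomRings():
        s = set(atom_ring)
        if s != mc and s & sub:
            n += 1
    return n


def _peptide_index(c):
    """Assumed formula: 3 x (ring amide bonds) / N, clipped to [0, 1].
    A pure cyclic peptide backbone (one amide per residue of three ring
    atoms) scores exactly 1; an amide-free macrolide scores 0."""
    return min(1.0, 3.0 * c.ring_amides / c.decomp.N)


def _periph_sub_ratio(c):
    return (len(c.peripheral_atoms) + 1) / (len(c.substituent_atoms) + 1)


# --------------------------------------------------------------------------
# the manifest
# --------------------------------------------------------------------------

def _build_registry() -> dict[int, DescriptorSpec]:
    S = DescriptorSpec
    HYB = Chem.HybridizationType
    specs = [
        # ---- 32 classic descriptors --------------------------------------
        S(1, "MW", "classic", "classic", scaling_kind="continuous", func=_mw),
        S(2, "HBD", "classic", "classic", func=_hbd),
        S(3, "HBA", "classic", "classic", func=_hba),
        S(4, "NRB", "classic", "classic", func=_nrb),
        S(5, "HeavyAtoms", "classic", "classic", func=_heavy),
        S(6, "CLogP", "classic", "classic", scaling_kind="continuous", func=_clogp),
        S(7, "RingCount", "classic", "classic", func=_nrings),
        S(8, "tPSA", "classic", "classic", scaling_kind="continuous", func=_tpsa),
        S(9, "AromaticRings", "classic", "classic", func=_narom_rings),
        S(10, "Fsp3", "classic", "classic", bounded01=True, func=_fsp3),
        S(11, "ChiralCenters", "classic", "classic", func=_chiral),
        S(12, "NCount", "classic", "classic", func=_elem_count("N")),
        S(13, "OCount", "classic", "classic", func=_elem_count("O")),
        S(14, "SCount", "classic", "classic", func=_elem_count("S")),
        S(15, "HalogenCount", "classic", "classic", func=_halogen_count),
        S(17, "AmideBonds", "classic", "classic", func=_amide_count),
        S(19, "AromaticAtoms", "classic", "classic", func=_aromatic_atoms),
        S(20, "Sp3Carbons", "classic", "classic", func=_carbons_hyb(HYB.SP3)),
        S(21, "Sp2Carbons", "classic", "classic", func=_carbons_hyb(HYB.SP2)),
        S(23, "Heteroatoms", "classic", "classic", func=_heteroatoms),
        S(24, "CCount", "classic", "classic", func=_elem_count("C")),
        S(25, "SaturatedRings", "classic", "classic",
          func=lambda c: rdMolDescriptors.CalcNumSaturatedRings(c.mol)),
        S(26, "AromaticHeterocycles", "classic", "classic",
          func=lambda c: rdMolDescriptors.CalcNumAromaticHeterocycles(c.mol)),
        S(27, "AliphaticRings", "classic", "classic",
          func=lambda c: rdMolDescriptors.CalcNumAliphaticRings(c.mol)),
        S(28, "MolMR", "classic", "classic", func=lambda c: Crippen.MolMR(c.mol)),
        S(29, "LabuteASA", "classic", "classic",
          func=lambda c: rdMolDescriptors.CalcLabuteASA(c.mol)),
        S(30, "BertzCT", "classic", "classic",
          func=lambda c: GraphDescriptors.BertzCT(c.mol)),
        S(31, "BalabanJ", "classic", "classic",
          func=lambda c: GraphDescriptors.BalabanJ(c.mol)),
        S(32, "Kappa1", "classic", "classic",
          func=lambda c: rdMolDescriptors.CalcKappa1(c.mol)),
        S(33, "Kappa2", "classic", "classic",
          func=lambda c: rdMolDescriptors.CalcKappa2(c.mol)),
        S(34, "Kappa3", "classic", "classic",
          func=lambda c: rdMolDescriptors.CalcKappa3(c.mol)),
        S(36, "AbsFormalCharge", "classic", "classic", func=_abs_charge),
        # ---- 12 prior-guideline descriptors ------------------------------
        S(18, "ChiralCenters/HA", "normalized", "guideline", bounded01=True,
          func=_chiral_per_ha),
        S(22, "RingHet/N", "normalized", "guideline", bounded01=True,
          func=_ring_het_per_n),
        S(37, "PeriphHA", "peripheral", "guideline", func=_periph_ha),
        S(38, "PeriphMethyls", "peripheral", "guideline", func=_periph_methyl),
        S(39, "PeriphOCount", "peripheral", "guideline", func=_periph_o),
        S(40, "SubstituentCount", "substituent", "guideline", func=_sub_count),
        S(41, "RingSizeN", "size-composition", "guideline", func=_ring_size),
        S(42, "PeriphHA/N", "normalized", "guideline", func=_periph_per_n),
        S(43, "SubstHA/HA", "normalized", "guideline", bounded01=True,
          func=_sub_ha_per_ha),
        S(44, "RingHA/HA", "normalized", "guideline", bounded01=True,
          func=_ring_ha_per_ha),
        S(45, "PeriphCCount", "peripheral", "guideline", func=_periph_c),
        S(47, "PeriphNCount", "peripheral", "guideline", func=_periph_n),
        # ---- 46 macrocycle-specific descriptors --------------------------
        S(16, "(PeriphN+1)/(PeriphO+1)", "peripheral", "novel", func=_periph_ratio_no),
        S(35, "SpiroRings", "substituent", "novel", func=_spiro_rings),
        S(46, "PeriphO/PeriphHA", "peripheral", "novel", bounded01=True,
          func=_periph_frac("O")),
        S(48, "PeriphHalogens", "peripheral", "novel", func=_periph_halogens),
        S(49, "PeriphS/PeriphHA", "peripheral", "novel", bounded01=True,
          func=_periph_frac("S")),
        S(50, "PeriphN/PeriphHA", "peripheral", "novel", bounded01=True,
          func=_periph_frac("N")),
        S(51, "PeriphC/PeriphHA", "peripheral", "novel", bounded01=True,
          func=_periph_frac("C")),
        S(52, "PeriphHal/PeriphHA", "peripheral", "novel", bounded01=True,
          func=_periph_halogen_frac),
        S(53, "RingCCount", "size-composition", "novel", func=_ring_elem("C")),
        S(54, "RingNCount", "size-composition", "novel", func=_ring_elem("N")),
        S(55, "RingOCount", "size-composition", "novel", func=_ring_elem("O")),
        S(56, "RingSCount", "size-composition", "novel", func=_ring_elem("S")),
        S(57, "RingHetCount", "size-composition", "novel", func=_ring_het_count),
        S(58, "RingPiBonds", "rigidity", "novel", func=_ring_pi_bonds),
        S(59, "RingAmideBonds", "rigidity", "novel", func=_ring_amide_count),
        S(60, "RingSp3CFraction", "rigidity", "novel", bounded01=True,
          func=_ring_sp3c_frac),
        S(61, "RingAromaticFraction", "rigidity", "novel", bounded01=True,
          func=_ring_aromatic_frac),
        S(62, "SubstHA", "substituent", "novel", func=_sub_ha),
        S(63, "SubstCCount", "substituent", "novel", func=_sub_c),
        S(64, "Substituent Fsp3", "substituent", "novel", bounded01=True,
          func=_sub_fsp3),
        S(65, "SubstOCount", "substituent", "novel", func=_sub_o),
        S(66, "SubstNCount", "substituent", "novel", func=_sub_n),
        S(67, "SubstO/SubstHA", "substituent", "novel", bounded01=True,
          func=_sub_o_frac),
        S(68, "SubstN/SubstHA", "substituent", "novel", bounded01=True,
          func=_sub_n_frac),
        S(69, "MaxSubstSize", "substituent", "novel", func=_max_sub),
        S(70, "MinSubstSize", "substituent", "novel", func=_min_sub),
        S(71, "MeanSubstSize", "substituent", "novel", func=_mean_sub),
        S(72, "MaxGapSize", "gap", "novel", func=_gap_max),
        S(73, "MinGapSize", "gap", "novel", func=_gap_min),
        S(74, "MeanGapSize", "gap", "novel", func=_gap_mean),
        S(75, "StDevGapSize", "gap", "novel", func=_gap_stdev),
        S(76, "Max gap size/N", "normalized", "novel", bounded01=True,
          func=_gap_max_n),
        S(77, "Min gap size/N", "normalized", "novel", bounded01=True,
          func=_gap_min_n),
        S(78, "MeanGapSize/N", "normalized", "novel", bounded01=True,
          func=_gap_mean_n),
        S(79, "St. dev of gap size/N", "normalized", "novel", bounded01=True,
          func=_gap_stdev_n),
        S(80, "AttachmentPoints", "gap", "novel", func=_attach_count),
        S(81, "AttachmentPoints/N", "normalized", "novel", bounded01=True,
          func=_attach_per_n),
        S(82, "Restricted fraction", "rigidity", "novel", bounded01=True,
          func=_restricted),
        S(83, "RingFusionBonds", "rigidity", "novel", func=_ring_fusion_bonds),
        S(84, "FusedSubstituents", "substituent", "novel", func=_fused_sub_count),
        S(85, "RingComplexity", "normalized", "novel", bounded01=True,
          reconstructed=True, func=_ring_complexity),
        S(86, "StDevSubstSize", "substituent", "novel", func=_stdev_sub),
        S(87, "SubstAromaticFraction", "substituent", "novel", bounded01=True,
          func=_sub_aromatic_frac),
        S(88, "SubstRingCount", "substituent", "novel", func=_sub_ring_count),
        S(89, "Peptide character index", "rigidity", "novel", bounded01=True,
          reconstructed=True, func=_peptide_index),
        S(90, "(PeriphHA+1)/(SubstHA+1)", "other", "novel", func=_periph_sub_ratio),
    ]
    registry = {s.mold_id: s for s in specs}
    assert len(registry) == 90, f"registry has {len(registry)} entries"
    return registry


_REGISTRY = _build_registry()

#: the 13 key descriptors used by the oral-druglikeness filter
KEY_PROPERTY_IDS = (35, 46, 79, 8, 16, 64, 77, 6, 76, 89, 82, 18, 22)


def registry_manifest() -> list[DescriptorSpec]:
    """All registered descriptors, ordered by mold_id."""
    return [spec for _, spec in sorted(_REGISTRY.items())]


def get_spec(mold_id: int) -> DescriptorSpec:
    return _REGISTRY[mold_id]


def compute_descriptor_vector(
    mol: Chem.Mol,
    decomp: MCDecomposition | None = None,
    *,
    min_ring_size: int = 11,
    multifusion_policy: str = "merge",
) -> DescriptorVector:
    """Evaluate every registered descriptor for one compound.

    With ``multifusion_policy="merge"`` a peri-fused ring system is treated
    as one fused substituent (the default). With ``"exception"`` the vector
    is still computed but flagged ``incomplete`` so callers can route the
    compound to an exceptions output.
    """
    if multifusion_policy not in ("merge", "exception"):
        raise ValueError(f"unknown multifusion policy {multifusion_policy!r}")
    if decomp is None:
        decomp = decompose(mol, min_ring_size=min_ring_size)
    ctx = DescriptorContext(mol, decomp)
    mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    values: dict[int, float] = {}
    exceptions: list[tuple[int, str]] = []
    for mold_id, spec in sorted(_REGISTRY.items()):
        try:
            values[mold_id] = float(spec.func(ctx))
        except ZeroDenominator:
            values[mold_id] = 0.0
            exceptions.append((mold_id, "zero denominator"))
        except Exception as exc:  # pragma: no cover - defensive
            values[mold_id] = 0.0
            exceptions.append((mold_id, f"{type(exc).__name__}: {exc}"))
    incomplete = decomp.multifusion and multifusion_policy == "exception"
    if incomplete:
        exceptions.append((0, "multifusion exception"))
    return DescriptorVector(compound_id=mol_id, values=values,
                            exceptions=exceptions, incomplete=incomplete)


def descriptor_matrix(records, *, min_ring_size: int = 11,
                      multifusion_policy: str = "merge"):
    """Compound-by-descriptor table for a list of MoleculeRecord (or any
    objects with ``id`` and ``mol``). Columns are integer mold_ids; rows
    indexed by compound id. Incomplete (multifusion-exception) vectors are
    skipped and reported in the second return value."""
    import pandas as pd

    rows, index, skipped = [], [], []
    for rec in records:
        vec = compute_descriptor_vector(
            rec.mol, min_ring_size=min_ring_size,
            multifusion_policy=multifusion_policy)
        if vec.incomplete:
            skipped.append((rec.id, "multifusion exception"))
            continue
        rows.append(vec.values)
        index.append(rec.id)
    return pd.DataFrame(rows, index=index), skipped


def manifest_to_json() -> list[dict]:
    return [
        {
            "mold_id": s.mold_id,
            "name": s.name,
            "category": s.category,
            "origin": s.origin,
            "mc_specific": s.mc_specific,
            "scaling_kind": s.scaling_kind,
            "bounded01": s.bounded01,
            "reconstructed": s.reconstructed,
        }
        for s in registry_manifest()
    ]
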