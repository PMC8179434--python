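"""Programmatic macrocycle generator with construction-time ground truth.

Molecules are assembled atom by atom from a :class:`GeneratorSpec`, so the
ring / peripheral / substituent partition, gap profile, rigidity and the
key descriptor values are known *by construction* — independently of the
decomposition module they are used to test. Profiles bias the sampled
specs toward ("oral-like") or away from ("sparse") the packaged
oral-druglike property ranges.

Vocabulary emitted: all-carbon or O/N-containing MC rings, ring amides
(N-C(=O) in the ring with a peripheral carbonyl O), ring C=C double bonds,
peripheral methyl / hydroxyl / carbonyl-O / halogen groups, and alkyl,
ether, aryl, ring-fused, or spiro substituents. Peri-fused (multifusion)
systems are produced only by :func:`generate_multifusion_example` for
exception-path tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem

from mcspace.decomposition import MCDecomposition, SubstituentGroup

PERIPHERAL_GROUPS = ("methyl", "hydroxyl", "carbonyl-O", "halogen")
SUBSTITUENT_KINDS = ("alkyl", "ether", "aryl", "fused", "spiro")


class GeneratorError(ValueError):
    """Spec is chemically unsatisfiable; message names the constraint."""


@dataclass(frozen=True)
class SubstituentSpec:
    position: int
    size: int
    kind: str = "alkyl"          # alkyl | ether | aryl | fused | spiro

    @property
    def fused(self) -> bool:
        return self.kind == "fused"

    @property
    def spiro(self) -> bool:
        return self.kind == "spiro"


@dataclass(frozen=True)
class GeneratorSpec:
    ring_size: int
    ring_oxygens: tuple[int, ...] = ()
    ring_nitrogens: tuple[int, ...] = ()
    ring_amides: tuple[int, ...] = ()       # position of the amide N; C=O at pos+1
    ring_double_bonds: tuple[int, ...] = () # C=C between pos and pos+1
    peripheral_plan: tuple[tuple[int, str], ...] = ()
    substituent_plan: tuple[SubstituentSpec, ...] = ()
    seed: int = 0


@dataclass
class GeneratedMol:
    id: str
    smiles: str
    mol: Chem.Mol
    spec: GeneratorSpec
    decomposition: MCDecomposition      # ground truth, construction indices
    expected: dict[int, float]          # mold_id -> expected value
    expected_exceptions: set[int] = field(default_factory=set)


def _validate(spec: GeneratorSpec) -> None:
    n = spec.ring_size
    if n < 11:
        raise GeneratorError(f"ring_size {n} < 11")
    occupied: set[int] = set()

    def claim(pos: int, what: str) -> None:
        p = pos % n
        if p in occupied:
            raise GeneratorError(f"position {p} claimed twice (by {what})")
        occupied.add(p)

    for p in spec.ring_oxygens:
        claim(p, "ring oxygen")
    for p in spec.ring_nitrogens:
        claim(p, "ring nitrogen")
    for p in spec.ring_amides:
        claim(p, "amide N")
        claim(p + 1, "amide C=O")
    for p in spec.ring_double_bonds:
        claim(p, "double bond")
        claim(p + 1, "double bond")
    for p, group in spec.peripheral_plan:
        if group not in PERIPHERAL_GROUPS:
            raise GeneratorError(f"unknown peripheral group {group!r}")
        claim(p, f"peripheral {group}")
    for sub in spec.substituent_plan:
        if sub.kind not in SUBSTITUENT_KINDS:
            raise GeneratorError(f"unknown substituent kind {sub.kind!r}")
        if sub.size < 2:
            raise GeneratorError("substituent size must be >= 2")
        if sub.kind == "aryl" and sub.size < 6:
            raise GeneratorError("aryl substituent needs size >= 6")
        if sub.kind == "spiro":
            # spiro consumes both free valences of one sp3 ring carbon
            claim(sub.position, "spiro substituent")
        elif sub.kind == "fused":
            claim(sub.position, "fused substituent")
            claim(sub.position + 1, "fused substituent")
        else:
            claim(sub.position, f"{sub.kind} substituent")


def _build(spec: GeneratorSpec) -> tuple[Chem.Mol, MCDecomposition]:
    n = spec.ring_size
    rw = Chem.RWMol()
    element = {p % n: "O" for p in spec.ring_oxygens}
    element.update({p % n: "N" for p in spec.ring_nitrogens})
    for p in spec.ring_amides:
        element[p % n] = "N"
    for i in range(n):
        rw.AddAtom(Chem.Atom(element.get(i, "C")))
    for i in range(n):
        rw.AddBond(i, (i + 1) % n, Chem.BondType.SINGLE)
    for p in spec.ring_double_bonds:
        rw.GetBondBetweenAtoms(p % n, (p + 1) % n).SetBondType(Chem.BondType.DOUBLE)

    peripheral: dict[int, str] = {}
    for p in spec.ring_amides:
        o = rw.AddAtom(Chem.Atom("O"))
        rw.AddBond((p + 1) % n, o, Chem.BondType.DOUBLE)
        peripheral[o] = "O"

    for p, group in spec.peripheral_plan:
        if group == "methyl":
            a = rw.AddAtom(Chem.Atom("C"))
            rw.AddBond(p % n, a, Chem.BondType.SINGLE)
            peripheral[a] = "C"
        elif group == "hydroxyl":
            a = rw.AddAtom(Chem.Atom("O"))
            rw.AddBond(p % n, a, Chem.BondType.SINGLE)
            peripheral[a] = "O"
        elif group == "carbonyl-O":
            a = rw.AddAtom(Chem.Atom("O"))
            rw.AddBond(p % n, a, Chem.BondType.DOUBLE)
            peripheral[a] = "O"
        else:  # halogen
            a = rw.AddAtom(Chem.Atom("Cl"))
            rw.AddBond(p % n, a, Chem.BondType.SINGLE)
            peripheral[a] = "Cl"

    substituents: list[SubstituentGroup] = []
    for sub in spec.substituent_plan:
        pos = sub.position % n
        atoms: list[int] = []
        if sub.kind in ("alkyl", "ether"):
            prev = pos
            for j in range(sub.size):
                sym = "O" if (sub.kind == "ether" and j == 1) else "C"
                a = rw.AddAtom(Chem.Atom(sym))
                rw.AddBond(prev, a, Chem.BondType.SINGLE)
                atoms.append(a)
                prev = a
            substituents.append(SubstituentGroup(
                atoms=frozenset(atoms), attachment_ring_atoms=(pos,)))
        elif sub.kind == "aryl":
            ar = [rw.AddAtom(Chem.Atom("C")) for _ in range(6)]
            for j in range(6):
                bt = Chem.BondType.DOUBLE if j % 2 == 0 else Chem.BondType.SINGLE
                rw.AddBond(ar[j], ar[(j + 1) % 6], bt)
            rw.AddBond(pos, ar[0], Chem.BondType.SINGLE)
            atoms.extend(ar)
            prev = ar[3]  # para position carries the saturated tail
            for _ in range(sub.size - 6):
                a = rw.AddAtom(Chem.Atom("C"))
                rw.AddBond(prev, a, Chem.BondType.SINGLE)
                atoms.append(a)
                prev = a
            substituents.append(SubstituentGroup(
                atoms=frozenset(atoms), attachment_ring_atoms=(pos,)))
        elif sub.kind == "fused":
            prev = pos
            for _ in range(sub.size):
                a = rw.AddAtom(Chem.Atom("C"))
                rw.AddBond(prev, a, Chem.BondType.SINGLE)
                atoms.append(a)
                prev = a
            rw.AddBond(prev, (pos + 1) % n, Chem.BondType.SINGLE)
            substituents.append(SubstituentGroup(
                atoms=frozenset(atoms),
                attachment_ring_atoms=tuple(sorted((pos, (pos + 1) % n))),
                fused=True))
        else:  # spiro
            prev = pos
            for _ in range(sub.size):
                a = rw.AddAtom(Chem.Atom("C"))
                rw.AddBond(prev, a, Chem.BondType.SINGLE)
                atoms.append(a)
                prev = a
            rw.AddBond(prev, pos, Chem.BondType.SINGLE)
            substituents.append(SubstituentGroup(
                atoms=frozenset(atoms), attachment_ring_atoms=(pos,),
                spiro=True))

    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    decomp = MCDecomposition(
        ring_atoms=tuple(range(n)),
        peripheral_atoms=peripheral,
        substituents=substituents,
        multifusion=False,
    )
    return mol, decomp


def _gap_stats(positions: list[int], n: int) -> tuple[float, float, float, float, int]:
    """(max, min, mean, pstdev, k) of gaps between attachment positions —
    independent re-derivation from the construction plan."""
    k = len(positions)
    if k == 0:
        return float(n), float(n), float(n), 0.0, 0
    if k == 1:
        g = [n - 1]
    else:
        ps = sorted(positions)
        g = [(ps[(i + 1) % k] - ps[i]) % n - 1 for i in range(k)]
    mu = sum(g) / len(g)
    sd = math.sqrt(sum((x - mu) ** 2 for x in g) / len(g))
    return float(max(g)), float(min(g)), mu, sd, k


def _ring_amide_bonds(spec: GeneratorSpec) -> int:
    """Amide C-N bonds in the ring, from the plan. Counts planned amides
    plus emergent ones: any ring N adjacent to any ring carbonyl carbon
    (e.g. a peripheral carbonyl-O placed next to an amide N forms an
    imide with two amide bonds)."""
    n = spec.ring_size
    n_pos = {p % n for p in spec.ring_amides} | {p % n for p in spec.ring_nitrogens}
    c_pos = {(p + 1) % n for p in spec.ring_amides}
    c_pos |= {p % n for p, g in spec.peripheral_plan if g == "carbonyl-O"}
    count = 0
    for i in range(n):
        j = (i + 1) % n
        if (i in n_pos and j in c_pos) or (j in n_pos and i in c_pos):
            count += 1
    return count


def _expected_values(spec: GeneratorSpec) -> tuple[dict[int, float], set[int]]:
    n = spec.ring_size
    n_amides = len(spec.ring_amides)
    ring_het = len(spec.ring_oxygens) + len(spec.ring_nitrogens) + n_amides

    periph_o = n_amides
    periph_c = periph_hal = 0
    for _, group in spec.peripheral_plan:
        if group in ("hydroxyl", "carbonyl-O"):
            periph_o += 1
        elif group == "methyl":
            periph_c += 1
        else:
            periph_hal += 1
    periph_ha = periph_o + periph_c + periph_hal

    attach: set[int] = set()
    sub_c = sub_sp3c = sub_ha = 0
    n_fused = n_spiro = 0
    for sub in spec.substituent_plan:
        pos = sub.position % n
        attach.add(pos)
        sub_ha += sub.size
        if sub.kind == "alkyl":
            sub_c += sub.size
            sub_sp3c += sub.size
        elif sub.kind == "ether":
            sub_c += sub.size - 1
            sub_sp3c += sub.size - 1
        elif sub.kind == "aryl":
            sub_c += sub.size
            sub_sp3c += sub.size - 6
        elif sub.kind == "fused":
            attach.add((pos + 1) % n)
            n_fused += 1
            sub_c += sub.size
            sub_sp3c += sub.size
        else:
            n_spiro += 1
            sub_c += sub.size
            sub_sp3c += sub.size

    gmax, gmin, gmean, gsd, k = _gap_stats(sorted(attach), n)
    amide_bonds = _ring_amide_bonds(spec)
    restricted = (len(spec.ring_double_bonds) + amide_bonds + n_fused) / n

    expected: dict[int, float] = {
        41: float(n),
        22: ring_het / n,
        57: float(ring_het),
        59: float(amide_bonds),
        89: min(1.0, 3.0 * amide_bonds / n),
        82: restricted,
        35: float(n_spiro),
        84: float(n_fused),
        37: float(periph_ha),
        39: float(periph_o),
        45: float(periph_c),
        47: 0.0,
        16: 1.0 / (periph_o + 1),
        40: float(len(spec.substituent_plan)),
        62: float(sub_ha),
        63: float(sub_c),
        72: gmax, 73: gmin, 74: gmean, 75: gsd,
        76: gmax / n, 77: gmin / n, 78: gmean / n, 79: gsd / n,
        80: float(k),
    }
    exceptions: set[int] = set()
    if periph_ha > 0:
        expected[46] = periph_o / periph_ha
    else:
        expected[46] = 0.0
        exceptions.add(46)
    if sub_c > 0:
        expected[64] = sub_sp3c / sub_c
    else:
        expected[64] = 0.0
        exceptions.add(64)
    return expected, exceptions


def generate_macrocycle(spec: GeneratorSpec, mol_id: str = "gen") -> GeneratedMol:
    """Build one macrocycle from its spec with ground truth attached.

    Raises :class:`GeneratorError` naming the violated constraint when the
    spec is not chemically satisfiable.
    """
    _validate(spec)
    mol, decomp = _build(spec)
    expected, exceptions = _expected_values(spec)
    mol.SetProp("_Name", mol_id)
    return GeneratedMol(
        id=mol_id, smiles=Chem.MolToSmiles(mol), mol=mol, spec=spec,
        decomposition=decomp, expected=expected,
        expected_exceptions=exceptions,
    )


def generate_multifusion_example(ring_size: int = 12) -> Chem.Mol:
    """A macrocycle with two mutually fused rings bridging one MC bond —
    triggers the peri-fusion (multifusion) exception path."""
    rw = Chem.RWMol()
    for _ in range(ring_size):
        rw.AddAtom(Chem.Atom("C"))
    for i in range(ring_size):
        rw.AddBond(i, (i + 1) % ring_size, Chem.BondType.SINGLE)
    # ring A: 6-ring over MC bond (0, 1); ring B: 4-ring over the same bond
    a = [rw.AddAtom(Chem.Atom("C")) for _ in range(4)]
    rw.AddBond(1, a[0], Chem.BondType.SINGLE)
    for j in range(3):
        rw.AddBond(a[j], a[j + 1], Chem.BondType.SINGLE)
    rw.AddBond(a[3], 0, Chem.BondType.SINGLE)
    b = [rw.AddAtom(Chem.Atom("C")) for _ in range(2)]
    rw.AddBond(1, b[0], Chem.BondType.SINGLE)
    rw.AddBond(b[0], b[1], Chem.BondType.SINGLE)
    rw.AddBond(b[1], 0, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


# --------------------------------------------------------------------------
# library profiles
# --------------------------------------------------------------------------

def _sample_oral_like(rng: np.random.Generator) -> GeneratorSpec:
    """Targets drawn inside the packaged druglike ranges: dense decoration
    (small min gap, moderate max gap), 1-3 ring heteroatoms, peripheral mix
    dominated by oxygens, sp3 substituents, no spiro, low rigidity."""
    n = int(rng.integers(14, 19))
    # substituents: two adjacent-ish + one across the ring
    p3 = n // 2 + int(rng.integers(-1, 2))
    sub_positions = [0, 2, p3]
    sizes = rng.integers(2, 5, size=3)
    subs = tuple(SubstituentSpec(p, int(s), "alkyl")
                 for p, s in zip(sub_positions, sizes))
    used = {0, 2, p3}
    free = [i for i in range(n) if i not in used]
    rng.shuffle(free)

    def claim_pair() -> tuple[int, ...]:
        for i in list(free):
            if (i + 1) % n in free:
                free.remove(i)
                free.remove((i + 1) % n)
                return (i,)
        return ()

    ring_o = [free.pop()]
    if n >= 17:
        ring_o.append(free.pop())
    amides = claim_pair() if rng.random() < 0.5 else ()
    dbl = claim_pair() if rng.random() < 0.4 else ()

    # peripheral mix: oxygens (hydroxyl + one carbonyl + any amide C=O)
    # outnumber methyls by one, keeping PeriphO/PeriphHA near 0.5-0.67
    periph = [(free.pop(), "carbonyl-O")]
    n_oh = 2
    periph_o_total = n_oh + 1 + len(amides)
    n_me = periph_o_total - 1
    for _ in range(n_oh):
        if free:
            periph.append((free.pop(), "hydroxyl"))
    for _ in range(n_me):
        if free:
            periph.append((free.pop(), "methyl"))

    return GeneratorSpec(
        ring_size=n, ring_oxygens=tuple(ring_o), ring_amides=amides,
        ring_double_bonds=dbl, peripheral_plan=tuple(periph),
        substituent_plan=subs,
    )


def _sample_sparse(rng: np.random.Generator) -> GeneratorSpec:
    """Bare or nearly bare rings — outside most druglike ranges."""
    n = int(rng.integers(11, 22))
    periph = []
    if rng.random() < 0.3:
        periph.append((int(rng.integers(0, n)), "methyl"))
    return GeneratorSpec(ring_size=n, peripheral_plan=tuple(periph))


def _sample_kinase_like(rng: np.random.Generator) -> GeneratorSpec:
    """Smaller rings with aromatic substituents and ring unsaturation."""
    n = int(rng.integers(12, 16))
    subs = [SubstituentSpec(0, int(rng.integers(6, 9)), "aryl")]
    if rng.random() < 0.5:
        subs.append(SubstituentSpec(3, int(rng.integers(4, 7)), "fused"))
    dbl = (n // 2,) if rng.random() < 0.7 else ()
    ring_n = (n - 2,) if rng.random() < 0.5 else ()
    return GeneratorSpec(
        ring_size=n, ring_nitrogens=ring_n, ring_double_bonds=dbl,
        substituent_plan=tuple(subs),
    )


def _sample_random(rng: np.random.Generator) -> GeneratorSpec:
    sampler = rng.choice([_sample_oral_like, _sample_sparse, _sample_kinase_like])
    spec = sampler(rng)
    if rng.random() < 0.2:
        # occasionally add a spiro ring for variety
        n = spec.ring_size
        taken = {p % n for p in spec.ring_oxygens}
        taken |= {p % n for p in spec.ring_nitrogens}
        for p in spec.ring_amides:
            taken |= {p % n, (p + 1) % n}
        for p in spec.ring_double_bonds:
            taken |= {p % n, (p + 1) % n}
        taken |= {p % n for p, _ in spec.peripheral_plan}
        for s in spec.substituent_plan:
            taken |= {s.position % n}
            if s.kind == "fused":
                taken.add((s.position + 1) % n)
        open_pos = [i for i in range(n) if i not in taken]
        if open_pos:
            spiro = SubstituentSpec(int(rng.choice(open_pos)), 4, "spiro")
            spec = replace(spec, substituent_plan=spec.substituent_plan + (spiro,))
    return spec


_PROFILES = {
    "oral-like": _sample_oral_like,
    "sparse": _sample_sparse,
    "kinase-like": _sample_kinase_like,
    "random": _sample_random,
}


def generate_library(n: int, profile: str = "random", seed: int = 0,
                     out_smiles: str | None = None,
                     out_truth: str | None = None) -> tuple[list[GeneratedMol], pd.DataFrame]:
    """Generate *n* macrocycles from a named profile.

    Returns the generated molecules and a ground-truth table (one row per
    compound, columns ``mold_<id>`` for the construction-time expected
    descriptor values). Optionally writes a SMILES file and a truth CSV.
    """
    if n < 1:
        raise GeneratorError("n must be >= 1")
    if profile not in _PROFILES:
        raise GeneratorError(f"unknown profile {profile!r} (choose from {sorted(_PROFILES)})")
    rng = np.random.default_rng(seed)
    sampler = _PROFILES[profile]
    mols: list[GeneratedMol] = []
    for i in range(n):
        spec = sampler(rng)
        mols.append(generate_macrocycle(spec, mol_id=f"{profile}-{seed}-{i:04d}"))
    rows = []
    for gm in mols:
        row = {"id": gm.id, "smiles": gm.smiles, "ring_size": gm.spec.ring_size}
        row.update({f"mold_{k}": v for k, v in sorted(gm.expected.items())})
        rows.append(row)
    truth = pd.DataFrame(rows).set_index("id")
    if out_smiles:
        with open(out_smiles, "w", encoding="utf-8") as fh:
            for gm in mols:
                fh.write(f"{gm.smiles} {gm.id}\n")
    if out_truth:
        truth.to_csv(out_truth)
    return mols, truth
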