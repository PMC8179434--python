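"""Macrocycle ring perception and atom-class decomposition.

The macrocycle (MC) ring is taken to be the largest simple cycle of the
molecular graph, found by enumerating cycles inside each ring system — a
smallest-set-of-smallest-rings basis alone can miss bridged macrocycles.
Heavy atoms are then partitioned into three positional classes:

* ring atoms — members of the chosen MC cycle;
* peripheral atoms — single heavy atoms bonded to exactly one ring atom
  (methyl carbons, hydroxyl/carbonyl oxygens, halogens, imine nitrogens);
* substituent atoms — connected groups of >=2 heavy atoms attached to the
  ring, including rings fused or spiro-joined to the MC ring.

Gap statistics (ring atoms between substituent attachment points), the
restricted-bond fraction, and the multi-fusion exception test live here
because they are all functions of the decomposition.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem

logger = logging.getLogger(__name__)

DEFAULT_MIN_RING_SIZE = 11
DEFAULT_CYCLE_BUDGET = 200_000


class NoMacrocycleError(ValueError):
    """Raised when no simple cycle of the required size exists."""


class ComplexityExceededError(RuntimeError):
    """Raised when cycle enumeration exceeds the configured budget."""


@dataclass
class SubstituentGroup:
    """A connected group of heavy atoms attached to the MC ring.

    ``fused`` means the group bonds to >=2 distinct ring atoms (it closes a
    ring through the MC); ``spiro`` means the group contains a ring that
    shares exactly one atom with the MC ring.
    """

    atoms: frozenset[int]
    attachment_ring_atoms: tuple[int, ...]
    fused: bool = False
    spiro: bool = False

    @property
    def size(self) -> int:
        return len(self.atoms)


@dataclass
class MCDecomposition:
    ring_atoms: tuple[int, ...]          # cycle order
    peripheral_atoms: dict[int, str]     # atom index -> element symbol
    substituents: list[SubstituentGroup]
    multifusion: bool = False

    @property
    def N(self) -> int:
        """Ring size — the normalizer for the per-ring-atom descriptors."""
        return len(self.ring_atoms)

    @property
    def substituent_atoms(self) -> frozenset[int]:
        out: set[int] = set()
        for sub in self.substituents:
            out |= sub.atoms
        return frozenset(out)

    def atom_class(self, idx: int) -> str:
        if idx in self.ring_atoms:
            return "ring"
        if idx in self.peripheral_atoms:
            return "peripheral"
        return "substituent"

    def to_json_dict(self) -> dict:
        return {
            "ring_atoms": list(self.ring_atoms),
            "N": self.N,
            "peripheral_atoms": {str(k): v for k, v in self.peripheral_atoms.items()},
            "substituents": [
                {
                    "atoms": sorted(s.atoms),
                    "attachment_ring_atoms": list(s.attachment_ring_atoms),
                    "fused": s.fused,
                    "spiro": s.spiro,
                }
                for s in self.substituents
            ],
            "multifusion": self.multifusion,
        }


@dataclass
class GapProfile:
    gaps: list[int]
    n_attachment_points: int
    N: int
    max_gap: float = field(init=False)
    min_gap: float = field(init=False)
    mean_gap: float = field(init=False)
    stdev_gap: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_attachment_points == 0:
            # undecorated ring: maximally sparse by convention
            self.max_gap = self.min_gap = self.mean_gap = float(self.N)
            self.stdev_gap = 0.0
        else:
            self.max_gap = float(max(self.gaps))
            self.min_gap = float(min(self.gaps))
            self.mean_gap = statistics.fmean(self.gaps)
            self.stdev_gap = statistics.pstdev(self.gaps)

    def normalized(self) -> tuple[float, float, float, float]:
        """(max, min, mean, stdev) each divided by ring size N."""
        return (self.max_gap / self.N, self.min_gap / self.N,
                self.mean_gap / self.N, self.stdev_gap / self.N)


def _mol_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(a.GetIdx() for a in mol.GetAtoms())
    g.add_edges_from((b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds())
    return g


def _canonical_cycle(cycle: list[int]) -> tuple[int, ...]:
    """Rotate/reflect a cycle so it starts at its smallest atom index and
    proceeds toward the smaller of the two neighbors. Makes the returned
    ring order deterministic regardless of enumeration order."""
    n = len(cycle)
    start = cycle.index(min(cycle))
    forward = [cycle[(start + i) % n] for i in range(n)]
    backward = [cycle[(start - i) % n] for i in range(n)]
    return tuple(forward) if forward[1] <= backward[1] else tuple(backward)


def _has_chord(cycle: list[int], adj: dict[int, set[int]]) -> bool:
    """True if any graph edge joins two non-consecutive cycle atoms."""
    n = len(cycle)
    pos = {a: i for i, a in enumerate(cycle)}
    for i, a in enumerate(cycle):
        for b in adj[a]:
            j = pos.get(b)
            if j is None:
                continue
            if abs(i - j) not in (1, n - 1) and i != j:
                return True
    return False


def largest_simple_cycle(mol: Chem.Mol, budget: int = DEFAULT_CYCLE_BUDGET) -> tuple[int, ...] | None:
    """Largest chordless simple cycle over the ring-bond subgraph, or None
    if the molecule is acyclic.

    Cycles are enumerated within ring systems rather than taken from a
    smallest-set-of-smallest-rings basis (which can miss bridged
    macrocycles). Cycles with a chord are discarded: for a macrocycle
    ortho-fused to a benzene ring this rejects the envelope cycle that
    detours around the benzene (the fusion bond is its chord) and returns
    the macrocycle itself. Ties on size break toward the smallest
    lexicographic sorted atom tuple. Enumeration beyond *budget* cycles
    raises :class:`ComplexityExceededError`.
    """
    ring_edges = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx())
        for b in mol.GetBonds() if b.IsInRing()
    ]
    if not ring_edges:
        return None
    sub = nx.Graph(ring_edges)
    adj = {n: set(sub.neighbors(n)) for n in sub.nodes}
    best: tuple[int, ...] | None = None
    best_key: tuple[int, tuple[int, ...]] | None = None
    count = 0
    for cycle in nx.simple_cycles(sub):
        count += 1
        if count > budget:
            raise ComplexityExceededError(
                f"cycle enumeration exceeded budget of {budget}")
        if len(cycle) > 3 and _has_chord(cycle, adj):
            continue
        key = (-len(cycle), tuple(sorted(cycle)))
        if best_key is None or key < best_key:
            best_key = key
            best = _canonical_cycle(cycle)
    return best


def find_mc_ring(mol: Chem.Mol, min_ring_size: int = DEFAULT_MIN_RING_SIZE,
                 budget: int = DEFAULT_CYCLE_BUDGET) -> tuple[int, ...]:
    """Return the MC ring as an ordered atom-index cycle.

    Raises
    ------
    NoMacrocycleError
        If the largest simple cycle has fewer than *min_ring_size* atoms.
    ComplexityExceededError
        If cycle enumeration exceeds *budget* (caller should route the
        compound to the exceptions output).
    """
    cycle = largest_simple_cycle(mol, budget=budget)
    if cycle is None or len(cycle) < min_ring_size:
        found = 0 if cycle is None else len(cycle)
        raise NoMacrocycleError(
            f"largest ring {found} < min ring size {min_ring_size}")
    return cycle


def classify_atoms(mol: Chem.Mol, ring: tuple[int, ...]) -> MCDecomposition:
    """Partition heavy atoms into ring / peripheral / substituent classes.

    Non-ring atoms are grouped into connected components of the graph with
    the ring removed. A single-atom component bonded to exactly one ring
    atom is peripheral; everything else is a substituent group. A
    single-atom bridge bonded to two ring atoms is treated as a (fused)
    substituent, not a peripheral atom.
    """
    g = _mol_graph(mol)
    ring_set = set(ring)
    rest = g.subgraph(n for n in g.nodes if n not in ring_set)

    peripheral: dict[int, str] = {}
    substituents: list[SubstituentGroup] = []
    for comp in sorted(nx.connected_components(rest), key=min):
        attachments = sorted({
            nbr for a in comp for nbr in g.neighbors(a) if nbr in ring_set})
        if len(comp) == 1 and len(attachments) == 1:
            idx = next(iter(comp))
            peripheral[idx] = mol.GetAtomWithIdx(idx).GetSymbol()
            continue
        fused = len(attachments) >= 2
        spiro = False
        if len(attachments) == 1:
            r = attachments[0]
            bonds_into_comp = sum(1 for nbr in g.neighbors(r) if nbr in comp)
            spiro = bonds_into_comp >= 2
        substituents.append(SubstituentGroup(
            atoms=frozenset(comp),
            attachment_ring_atoms=tuple(attachments),
            fused=fused, spiro=spiro,
        ))
    decomp = MCDecomposition(
        ring_atoms=tuple(ring), peripheral_atoms=peripheral,
        substituents=substituents,
    )
    decomp.multifusion = detect_multifusion(decomp, mol)
    return decomp


def decompose(mol: Chem.Mol, min_ring_size: int = DEFAULT_MIN_RING_SIZE,
              budget: int = DEFAULT_CYCLE_BUDGET) -> MCDecomposition:
    """find_mc_ring + classify_atoms in one call."""
    return classify_atoms(mol, find_mc_ring(mol, min_ring_size, budget))


def detect_multifusion(decomp: MCDecomposition, mol: Chem.Mol) -> bool:
    """True iff >=2 non-MC rings each share >=2 atoms with the MC ring and
    share >=1 bond with each other (peri-fusion). Such systems cannot be
    divided unambiguously into separate fused substituents."""
    ring_info = mol.GetRingInfo()
    mc = set(decomp.ring_atoms)
    candidates = []
    for atom_ring in ring_info.AtomRings():
        s = set(atom_ring)
        if s == mc:
            continue
        if len(s & mc) >= 2:
            bonds = set()
            n = len(atom_ring)
            for i in range(n):
                a, b = atom_ring[i], atom_ring[(i + 1) % n]
                bonds.add(frozenset((a, b)))
            candidates.append(bonds)
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            if candidates[i] & candidates[j]:
                return True
    return False


def attachment_positions(decomp: MCDecomposition) -> list[int]:
    """Ring positions (indices into the cycle order) bonded to >=1
    substituent group. A ring atom bearing several groups counts once."""
    attached: set[int] = set()
    for sub in decomp.substituents:
        attached.update(sub.attachment_ring_atoms)
    return [i for i, a in enumerate(decomp.ring_atoms) if a in attached]


def _attachment_positions_with_peripheral(decomp: MCDecomposition, mol: Chem.Mol) -> list[int]:
    g = _mol_graph(mol)
    attached: set[int] = set()
    for sub in decomp.substituents:
        attached.update(sub.attachment_ring_atoms)
    for p in decomp.peripheral_atoms:
        for nbr in g.neighbors(p):
            if nbr in decomp.ring_atoms:
                attached.add(nbr)
    return [i for i, a in enumerate(decomp.ring_atoms) if a in attached]


def compute_gaps(decomp: MCDecomposition, mol: Chem.Mol | None = None,
                 include_peripheral: bool = False) -> GapProfile:
    """Gap profile: runs of unattached ring atoms between consecutive
    substituent attachment points, walking the ring cycle once.

    Conventions (ring size N): one attachment point → gaps = [N-1]; zero
    attachment points → no gaps, max = min = mean = N, stdev = 0. With >=1
    attachment point, sum(gaps) + #attachment points = N. Stdev is the
    population standard deviation.

    ``include_peripheral=True`` also counts peripheral-bearing ring atoms
    as attachment points (needs *mol*); used by the ring-complexity mode.
    """
    if include_peripheral:
        if mol is None:
            raise ValueError("include_peripheral requires the molecule")
        positions = _attachment_positions_with_peripheral(decomp, mol)
    else:
        positions = attachment_positions(decomp)
    N = decomp.N
    k = len(positions)
    if k == 0:
        return GapProfile(gaps=[], n_attachment_points=0, N=N)
    if k == 1:
        return GapProfile(gaps=[N - 1], n_attachment_points=1, N=N)
    gaps = []
    for i in range(k):
        a = positions[i]
        b = positions[(i + 1) % k]
        gaps.append((b - a - 1) % N if i < k - 1 else N - a + positions[0] - 1)
    return GapProfile(gaps=gaps, n_attachment_points=k, N=N)


def _is_amide_cn(mol: Chem.Mol, u: int, v: int) -> bool:
    au, av = mol.GetAtomWithIdx(u), mol.GetAtomWithIdx(v)
    pair = {au.GetSymbol(), av.GetSymbol()}
    if pair != {"C", "N"}:
        return False
    carbon = au if au.GetSymbol() == "C" else av
    for nbr in carbon.GetNeighbors():
        if nbr.GetSymbol() == "O":
            b = mol.GetBondBetweenAtoms(carbon.GetIdx(), nbr.GetIdx())
            if b is not None and b.GetBondType() == Chem.BondType.DOUBLE:
                return True
    return False


def ring_bond_restrictions(decomp: MCDecomposition, mol: Chem.Mol) -> list[bool]:
    """Per-ring-bond flag: bond is a pi bond, an amide C-N bond, or shared
    with another ring (endpoints still connected after deleting every MC
    ring bond). Order follows the ring cycle, bond i = (atom i, atom i+1)."""
    ring = decomp.ring_atoms
    N = decomp.N
    g = _mol_graph(mol)
    h = g.copy()
    for i in range(N):
        h.remove_edge(ring[i], ring[(i + 1) % N])
    comp_id: dict[int, int] = {}
    for ci, comp in enumerate(nx.connected_components(h)):
        for n in comp:
            comp_id[n] = ci

    flags = []
    for i in range(N):
        u, v = ring[i], ring[(i + 1) % N]
        bond = mol.GetBondBetweenAtoms(u, v)
        pi = bond.GetIsAromatic() or bond.GetBondTypeAsDouble() > 1.0
        amide = _is_amide_cn(mol, u, v)
        fused = comp_id[u] == comp_id[v]
        flags.append(pi or amide or fused)
    return flags


def restricted_fraction(decomp: MCDecomposition, mol: Chem.Mol) -> float:
    """Fraction of MC ring bonds rigidified beyond plain ring membership."""
    flags = ring_bond_restrictions(decomp, mol)
    return sum(flags) / decomp.N


def ring_amide_bond_count(decomp: MCDecomposition, mol: Chem.Mol) -> int:
    """Number of amide C-N bonds lying in the MC ring itself."""
    ring = decomp.ring_atoms
    N = decomp.N
    return sum(
        1 for i in range(N)
        if _is_amide_cn(mol, ring[i], ring[(i + 1) % N])
    )
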