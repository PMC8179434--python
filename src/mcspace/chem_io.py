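"""Structure file I/O and the macrocycle admission filter.

Molecules are carried as RDKit mols wrapped in :class:`MoleculeRecord` with
an id and file provenance. Reading is permissive: unparsable entries are
logged and skipped, multi-component entries are stripped to their largest
covalent component, and duplicate ids are disambiguated with an ordinal
suffix. Only a zero-parse result is fatal.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# RDKit's own parse warnings are noisy on deliberately bad test input.
RDLogger.DisableLog("rdApp.error")


class InputError(ValueError):
    """Missing file, unknown format, or zero parsable entries."""


@dataclass
class MoleculeRecord:
    """One parsed structure: id, RDKit mol (implicit H), and provenance."""

    id: str
    mol: Chem.Mol
    source: str = ""

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


@dataclass
class FilterReport:
    kept: list[str]
    excluded: list[tuple[str, str]]
    min_ring_size: int
    kept_records: list[MoleculeRecord] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        rows = [{"id": i, "status": "kept", "reason": ""} for i in self.kept]
        rows += [{"id": i, "status": "excluded", "reason": r} for i, r in self.excluded]
        return rows


def _largest_fragment(mol: Chem.Mol, mol_id: str) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    largest = max(frags, key=lambda f: f.GetNumHeavyAtoms())
    logger.info(
        "%s: multi-component entry, kept largest covalent component (%d of %d atoms)",
        mol_id, largest.GetNumHeavyAtoms(), mol.GetNumHeavyAtoms(),
    )
    return largest


def _dedupe_id(mol_id: str, seen: dict[str, int]) -> str:
    n = seen.get(mol_id, 0)
    seen[mol_id] = n + 1
    if n == 0:
        return mol_id
    new_id = f"{mol_id}_{n + 1}"
    logger.warning("duplicate id %r renamed to %r", mol_id, new_id)
    return new_id


def read_structures(path: str, format: str | None = None) -> list[MoleculeRecord]:
    """Read SMILES (.smi) or SDF files into :class:`MoleculeRecord` lists.

    Parameters
    ----------
    path:
        File to read. When *format* is None it is inferred from the
        extension (``.smi``/``.smiles``/``.txt`` → smiles, ``.sdf``/``.sd``
        → sdf).
    format:
        ``"smiles"`` or ``"sdf"``.

    Returns
    -------
    list of MoleculeRecord, one per parsable entry in file order.

    Raises
    ------
    InputError
        If the file is missing, the format is unknown, or no entry parses.
    """
    if not os.path.exists(path):
        raise InputError(f"input file not found: {path}")
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {"": "smiles", ".smi": "smiles", ".smiles": "smiles",
                  ".txt": "smiles", ".sdf": "sdf", ".sd": "sdf"}.get(ext)
        if format is None:
            raise InputError(f"cannot infer format from extension of {path}")
    format = format.lower()
    if format not in ("smiles", "sdf"):
        raise InputError(f"unknown format {format!r} (expected 'smiles' or 'sdf')")

    records: list[MoleculeRecord] = []
    seen_ids: dict[str, int] = {}
    if format == "smiles":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                mol_id = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
                mol = Chem.MolFromSmiles(smiles)
                if mol is None:
                    logger.warning("%s:%d unparsable SMILES %r, skipped", path, lineno, smiles)
                    continue
                mol = _largest_fragment(mol, mol_id)
                records.append(MoleculeRecord(
                    id=_dedupe_id(mol_id, seen_ids), mol=mol,
                    source=f"{path}:{lineno}",
                ))
    else:
        supplier = Chem.SDMolSupplier(path, sanitize=True)
        for idx, mol in enumerate(supplier):
            if mol is None:
                logger.warning("%s: SDF entry %d unparsable, skipped", path, idx)
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{idx + 1}"
            mol = _largest_fragment(mol, mol_id)
            records.append(MoleculeRecord(
                id=_dedupe_id(mol_id, seen_ids), mol=mol,
                source=f"{path}#{idx}",
            ))

    if not records:
        raise InputError(f"no parsable entries in {path}")
    return records


def largest_ring_size(mol: Chem.Mol) -> int:
    """Size of the largest simple cycle in the molecule (0 if acyclic)."""
    # local import to avoid a cycle at package import time
    from mcspace.decomposition import largest_simple_cycle

    cycle = largest_simple_cycle(mol)
    return len(cycle) if cycle is not None else 0


def filter_macrocycles(records: list[MoleculeRecord], min_ring_size: int = 11) -> FilterReport:
    """Keep records whose largest ring has >= *min_ring_size* atoms."""
    if min_ring_size < 3:
        raise ValueError("min_ring_size must be >= 3")
    kept, kept_records, excluded = [], [], []
    for rec in records:
        size = largest_ring_size(rec.mol)
        if size >= min_ring_size:
            kept.append(rec.id)
            kept_records.append(rec)
        else:
            excluded.append((rec.id, f"largest ring {size} < {min_ring_size}"))
    return FilterReport(kept=kept, excluded=excluded,
                        min_ring_size=min_ring_size, kept_records=kept_records)


def write_smiles(records: list[MoleculeRecord], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"{rec.to_smiles()} {rec.id}\n")
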