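"""Oral-macrocycle-druglikeness property ranges and violation counting.

The packaged default range set holds the 13 key descriptors with their
80%-coverage value ranges over the oral macrocycle drug reference set.
New range sets can be derived from any sample given a distribution
modality per property: modalities A (normal) and C (bi/multimodal) take
the middle 80% (10th-90th percentile); modality B (unimodal, asymmetric)
anchors the 80% window at the biased extreme. Range bounds are inclusive.
A compound is classified "within" oral-MC-druglike property space when it
violates at most 4 of the 13 ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from mcspace.registry import DescriptorVector

VIOLATION_THRESHOLD = 4


@dataclass
class PropertyRange:
    mold_id: int
    lo: float
    hi: float
    modality: str = "A"
    name: str = ""

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi


@dataclass
class PropertyRangeSet:
    entries: list[PropertyRange]
    provenance: str = "derived"

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def mold_ids(self) -> list[int]:
        return [e.mold_id for e in self.entries]

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "entries": [
                {"mold_id": e.mold_id, "name": e.name, "lo": e.lo,
                 "hi": e.hi, "modality": e.modality}
                for e in self.entries
            ],
        }

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def from_json_dict(cls, data: dict) -> "PropertyRangeSet":
        entries = [
            PropertyRange(mold_id=e["mold_id"], lo=float(e["lo"]), hi=float(e["hi"]),
                          modality=e.get("modality", "A"), name=e.get("name", ""))
            for e in data["entries"]
        ]
        return cls(entries=entries, provenance=data.get("provenance", "derived"))

    @classmethod
    def load(cls, path: str) -> "PropertyRangeSet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json_dict(json.load(fh))


def load_table2_ranges() -> PropertyRangeSet:
    """The packaged 13-property oral-MC-druglike range set."""
    text = resources.files("mcspace.data").joinpath("table2_ranges.json").read_text("utf-8")
    return PropertyRangeSet.from_json_dict(json.loads(text))


def derive_ranges(values, modality: str, coverage: float = 0.80) -> tuple[float, float]:
    """80%-coverage range of a property sample under its modality.

    A / C: middle coverage, i.e. [10th, 90th] percentile at the default.
    B-low (low-end biased): [min, 80th percentile].
    B-high (high-end biased): [20th percentile, max].
    Linear-interpolation percentiles throughout.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    tail = 1.0 - coverage
    if modality in ("A", "C"):
        lo = float(np.quantile(x, tail / 2.0))
        hi = float(np.quantile(x, 1.0 - tail / 2.0))
    elif modality in ("B-low", "B"):
        lo = float(np.min(x))
        hi = float(np.quantile(x, coverage))
    elif modality == "B-high":
        lo = float(np.quantile(x, tail))
        hi = float(np.max(x))
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return lo, hi


def _vector_values(vector) -> dict[int, float]:
    if isinstance(vector, DescriptorVector):
        return vector.values
    return dict(vector)


def violation_flags(vector, ranges: PropertyRangeSet) -> dict[int, bool]:
    """Per-property out-of-range flags (True = violation)."""
    values = _vector_values(vector)
    flags = {}
    for entry in ranges:
        if entry.mold_id not in values:
            raise KeyError(f"descriptor mold_id {entry.mold_id} missing from vector")
        flags[entry.mold_id] = not entry.contains(values[entry.mold_id])
    return flags


def count_violations(vector, ranges: PropertyRangeSet) -> int:
    """Number of ranged properties falling outside their [lo, hi] bounds."""
    return sum(violation_flags(vector, ranges).values())


def classify(violations: int, threshold: int = VIOLATION_THRESHOLD) -> str:
    """"within" iff violations <= threshold, else "outside"."""
    if violations < 0:
        raise ValueError("violations must be >= 0")
    return "within" if violations <= threshold else "outside"
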