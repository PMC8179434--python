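"""Two-regime 0-100 scaling of the descriptor matrix.

Discrete descriptors (counts, ratios, everything except MW, tPSA and
clogP) are scaled from zero to the highest training value:
``100 * x / p_max``. The three continuous descriptors are scaled onto the
window spanning +/-2 standard deviations around the training mean:
``100 * (x - p_min) / (4 * sigma)`` with ``p_min = mu - 2*sigma``; values
beyond that window map to <0 or >100 and pass through un-clipped.

Parameters are fit on the training compounds once and reused verbatim when
projecting new designs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTINUOUS_MOLD_IDS = (1, 6, 8)  # MW, CLogP, tPSA


@dataclass
class ColumnScaling:
    kind: str                   # "discrete" | "continuous"
    p_max: float | None = None  # discrete
    mu: float | None = None     # continuous
    sigma: float | None = None
    constant: bool = False

    @property
    def p_min(self) -> float | None:
        if self.kind != "continuous":
            return None
        return self.mu - 2.0 * self.sigma


@dataclass
class ScalingParams:
    columns: dict[str, ColumnScaling] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        out = {}
        for col, cs in self.columns.items():
            d = {"kind": cs.kind, "constant": cs.constant}
            if cs.kind == "discrete":
                d["p_max"] = cs.p_max
            else:
                d.update(mu=cs.mu, sigma=cs.sigma, p_min=cs.p_min)
            out[col] = d
        return out

    @classmethod
    def from_json_dict(cls, data: dict) -> "ScalingParams":
        cols = {}
        for col, d in data.items():
            cols[col] = ColumnScaling(
                kind=d["kind"], p_max=d.get("p_max"),
                mu=d.get("mu"), sigma=d.get("sigma"),
                constant=d.get("constant", False))
        return cls(columns=cols)

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "ScalingParams":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json_dict(json.load(fh))


def _continuous_columns(matrix: pd.DataFrame, registry=None) -> set:
    """Columns scaled continuously: MW, tPSA, clogP. Matched either by a
    registry manifest (mold_id columns) or by the integer ids directly."""
    cont = set()
    for col in matrix.columns:
        mold_id = col if isinstance(col, int) else None
        if mold_id is None and isinstance(col, str) and col.startswith("mold_"):
            try:
                mold_id = int(col.split("_")[1])
            except (IndexError, ValueError):
                mold_id = None
        if mold_id in CONTINUOUS_MOLD_IDS:
            cont.add(col)
    return cont


def fit_scaling(matrix: pd.DataFrame, continuous: set | None = None) -> ScalingParams:
    """Fit per-column scaling parameters on the training matrix.

    ``continuous`` overrides the auto-detected {MW, CLogP, tPSA} column
    set. Zero-variance columns are flagged constant.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 compounds to fit scaling")
    if continuous is None:
        continuous = _continuous_columns(matrix)
    params = ScalingParams()
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        if col in continuous:
            mu = float(np.mean(x))
            sigma = float(np.std(x))  # population, matches variance usage
            if sigma == 0.0:
                params.columns[col] = ColumnScaling(
                    kind="continuous", mu=mu, sigma=1.0, constant=True)
            else:
                params.columns[col] = ColumnScaling(kind="continuous", mu=mu, sigma=sigma)
        else:
            p_max = float(np.max(x))
            constant = bool(np.max(x) == np.min(x))
            params.columns[col] = ColumnScaling(kind="discrete", p_max=p_max,
                                                constant=constant)
    return params


def apply_scaling(matrix: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Scale a descriptor matrix onto the 0-100 training frame.

    Discrete: 100*x/p_max (0 when p_max == 0). Continuous:
    100*(x - p_min)/(4*sigma), un-clipped outside [0, 100].
    """
    missing = [c for c in matrix.columns if c not in params.columns]
    if missing:
        raise KeyError(f"columns missing from scaling params: {missing}")
    out = {}
    for col in matrix.columns:
        cs = params.columns[col]
        x = matrix[col].to_numpy(dtype=float)
        if cs.kind == "discrete":
            out[col] = np.zeros_like(x) if cs.p_max == 0 else 100.0 * x / cs.p_max
        else:
            out[col] = 100.0 * (x - cs.p_min) / (4.0 * cs.sigma)
    return pd.DataFrame(out, index=matrix.index)


def invert_scaling(scaled: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Recover raw values from scaled ones (non-constant columns)."""
    out = {}
    for col in scaled.columns:
        cs = params.columns[col]
        z = scaled[col].to_numpy(dtype=float)
        if cs.kind == "discrete":
            out[col] = z * cs.p_max / 100.0
        else:
            out[col] = z * 4.0 * cs.sigma / 100.0 + cs.p_min
    return pd.DataFrame(out, index=scaled.index)
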