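"""Descriptor importance in the fitted PC space and redundancy pruning.

Importance of descriptor p over the first n PCs is the sum of its squared
loading coefficients weighted by its total (population) variance in the
scaled matrix: ``I_p = V_p * sum_i c_{p,i}^2``. Summed over *all* PCs the
squared loadings of a descriptor total 1 (orthonormal rows of V), so total
importance equals total variance.

Redundant descriptors among the top-ranked ones are pruned by clustering
on |Pearson correlation| >= a threshold and keeping only the
highest-importance member of each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mcspace.chem_space import ChemicalSpaceModel


@dataclass
class ImportanceTable:
    table: pd.DataFrame  # index = column id, columns: importance, variance, rank
    n_pcs: int
    retained: list = field(default_factory=list)

    def top(self, n: int) -> list:
        return list(self.table.index[:n])


def property_importance(model: ChemicalSpaceModel, scaled_matrix,
                        n_pcs: int = 10) -> ImportanceTable:
    """Rank descriptors by I_p = V_p * sum of squared loadings in PCs 1..n."""
    if n_pcs > model.n_components:
        raise ValueError(f"n_pcs {n_pcs} exceeds available PCs {model.n_components}")
    X = np.asarray(scaled_matrix, dtype=float)
    columns = list(scaled_matrix.columns) if hasattr(scaled_matrix, "columns") else list(range(X.shape[1]))
    variance = X.var(axis=0)  # population variance (divide by n)
    loadings_sq = (model.coefficients[:, :n_pcs] ** 2).sum(axis=1)
    importance = variance * loadings_sq
    df = pd.DataFrame({"importance": importance, "variance": variance}, index=columns)
    df = df.sort_values("importance", ascending=False, kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return ImportanceTable(table=df, n_pcs=n_pcs)


def prune_redundant(table: ImportanceTable, scaled_matrix, top_n: int = 20,
                    r_threshold: float = 0.8) -> list:
    """Among the top_n descriptors, keep one survivor per correlation
    cluster (|Pearson r| >= r_threshold links two descriptors; clusters
    are the connected components of that graph). The survivor is the
    cluster member with the highest importance. Deterministic.
    """
    if top_n > len(table.table):
        raise ValueError("top_n exceeds table size")
    top = table.top(top_n)
    X = pd.DataFrame(np.asarray(scaled_matrix, dtype=float),
                     columns=(list(scaled_matrix.columns)
                              if hasattr(scaled_matrix, "columns")
                              else list(range(np.asarray(scaled_matrix).shape[1]))))
    sub = X[top]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(np.corrcoef(sub.to_numpy(dtype=float), rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)  # constant columns correlate with nothing

    # union-find over the |r| >= threshold graph
    parent = list(range(len(top)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(top)):
        for j in range(i + 1, len(top)):
            if corr[i, j] >= r_threshold:
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(top)):
        clusters.setdefault(find(i), []).append(i)

    survivors = []
    for members in clusters.values():
        # top is already importance-ordered, so the first member wins
        survivors.append(top[min(members)])
    survivors.sort(key=lambda c: top.index(c))
    table.retained = survivors
    return survivors
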