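"""Representative-compound selection by PAM k-medoids on Z-scored data.

Columns are Z-scored (sample standard deviation) before Euclidean
distances are computed; constant columns carry no information for a
Z-score and are dropped with a log line. The solver is classic PAM:
greedy BUILD initialization followed by best-improvement swap iterations,
with seeded tie-breaking, so a given (matrix, k, seed) always returns the
same medoids and the total cost never increases between iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_K = 42


@dataclass
class SelectionResult:
    medoid_ids: list
    medoid_indices: list[int]
    assignment: dict            # id -> medoid id
    total_cost: float
    seed: int
    cost_history: list[float]


def _zscore(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.info("dropping %d constant column(s) before Z-scoring",
                    int((~keep).sum()))
    Xk = X[:, keep]
    return (Xk - Xk.mean(axis=0)) / sd[keep]


def _assignment_cost(D: np.ndarray, medoids: np.ndarray) -> tuple[float, np.ndarray]:
    sub = D[:, medoids]
    nearest = np.argmin(sub, axis=1)
    return float(sub[np.arange(len(D)), nearest].sum()), medoids[nearest]


def kmedoids_representatives(matrix, k: int = DEFAULT_K, seed: int = 0,
                             ids=None, max_iter: int = 100) -> SelectionResult:
    """Select k representative rows by PAM k-medoids.

    Parameters
    ----------
    matrix:
        Compound-by-descriptor table (DataFrame or array). Z-scored
        internally.
    k:
        Number of medoids; defaults to 42.
    seed:
        Seeds the tie-breaking among equal-cost choices.
    ids:
        Optional row identifiers; defaults to the DataFrame index or row
        numbers.
    """
    if ids is None:
        ids = list(matrix.index) if hasattr(matrix, "index") else None
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if ids is None:
        ids = list(range(n))
    if k > n:
        raise ValueError(f"k={k} exceeds number of compounds n={n}")

    rng = np.random.default_rng(seed)
    Z = _zscore(X)
    diff = Z[:, None, :] - Z[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=2))

    def tie_argmin(values: np.ndarray, candidates: np.ndarray) -> int:
        best = values.min()
        ties = candidates[np.isclose(values, best, rtol=0, atol=1e-12)]
        return int(rng.choice(ties)) if len(ties) > 1 else int(ties[0])

    # BUILD: first medoid minimizes total distance, then greedy additions
    medoids: list[int] = []
    totals = D.sum(axis=0)
    medoids.append(tie_argmin(totals, np.arange(n)))
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        candidates = np.array([i for i in range(n) if i not in medoids])
        gains = np.array([
            np.minimum(current, D[:, c]).sum() for c in candidates])
        medoids.append(tie_argmin(gains, candidates))

    med = np.array(sorted(medoids))
    cost, _ = _assignment_cost(D, med)
    history = [cost]

    # SWAP: best-improvement until no swap lowers the cost
    for _ in range(max_iter):
        best_cost, best_swap = cost, None
        med_set = set(med.tolist())
        for mi, m in enumerate(med):
            for h in range(n):
                if h in med_set:
                    continue
                trial = med.copy()
                trial[mi] = h
                c, _ = _assignment_cost(D, trial)
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (mi, h)
        if best_swap is None:
            break
        med[best_swap[0]] = best_swap[1]
        med = np.array(sorted(med))
        assert best_cost <= cost + 1e-9, "swap increased cost"
        cost = best_cost
        history.append(cost)

    _, nearest = _assignment_cost(D, med)
    assignment = {ids[i]: ids[nearest[i]] for i in range(n)}
    return SelectionResult(
        medoid_ids=[ids[i] for i in med],
        medoid_indices=med.tolist(),
        assignment=assignment,
        total_cost=cost,
        seed=seed,
        cost_history=history,
    )
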