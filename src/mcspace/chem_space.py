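"""PCA chemical-space model, hyperellipsoid volumes, and centroid distances.

PCA is plain mean-centered SVD with no Z-scoring (the descriptor matrix is
already on a common 0-100 frame). New compounds are projected with
``scores = (row - column_means) @ coefficients``. Loading-column signs are
fixed by forcing each column's largest-magnitude entry positive so results
are reproducible across linear-algebra backends.

A compound set's occupied volume is summarized as an axis-aligned
hyperellipsoid over the first ``dims`` PCs whose per-axis diameter is the
score range covering the middle ``coverage`` fraction of the set; its
``d``-dimensional volume is pi^(d/2)/Gamma(d/2+1) * prod(semi-axes), and
the "average radius" is the d-th root of the volume. Distances between
set centroids (or compound vs set centroid) are Euclidean over the first
``dims`` PCs, normalized by the PC1 semi-axis of the all-compound
"universe" ellipsoid (or optionally its full PC1 range).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ChemicalSpaceModel:
    column_means: np.ndarray        # (p,)
    coefficients: np.ndarray        # (p, k) orthonormal loading columns
    explained_variance: np.ndarray  # (k,) fractions, sum to 1 over all PCs
    columns: list = field(default_factory=list)
    n_pcs_retained: int = 10
    training_scores: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.coefficients.shape[1]

    def to_json_dict(self) -> dict:
        return {
            "column_means": self.column_means.tolist(),
            "coefficients": self.coefficients.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "columns": [str(c) for c in self.columns],
            "n_pcs_retained": self.n_pcs_retained,
        }

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "ChemicalSpaceModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            column_means=np.asarray(d["column_means"], dtype=float),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            explained_variance=np.asarray(d["explained_variance"], dtype=float),
            columns=d.get("columns", []),
            n_pcs_retained=d.get("n_pcs_retained", 10),
        )


@dataclass
class Hyperellipsoid:
    center: np.ndarray      # (d,) per-PC mean score
    ranges: np.ndarray      # (d,) score span covering `coverage` of the set
    coverage: float
    volume: float = field(init=False)
    avg_radius: float = field(init=False)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.ranges = np.asarray(self.ranges, dtype=float)
        d = len(self.ranges)
        a = self.semi_axes
        log_unit = (d / 2.0) * math.log(math.pi) - math.lgamma(d / 2.0 + 1.0)
        prod = float(np.prod(a))
        self.volume = math.exp(log_unit) * prod
        self.avg_radius = self.volume ** (1.0 / d) if self.volume > 0 else 0.0

    @property
    def dims(self) -> int:
        return len(self.ranges)

    @property
    def semi_axes(self) -> np.ndarray:
        return self.ranges / 2.0

    @property
    def a_pc1(self) -> float:
        """Semi-axis along PC1, the distance normalizer."""
        return float(self.semi_axes[0])


def fit_pca(scaled_matrix, n_pcs_retained: int = 10) -> ChemicalSpaceModel:
    """Fit PCA by SVD of the column-mean-centered matrix.

    Constant columns are retained (they contribute zero variance and get
    no influence on the scores). Explained-variance fractions cover all
    computed PCs and sum to 1.
    """
    columns = list(scaled_matrix.columns) if hasattr(scaled_matrix, "columns") else []
    X = np.asarray(scaled_matrix, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows to fit PCA")
    means = X.mean(axis=0)
    Xc = X - means
    # economy SVD; k = min(n-1, p) informative components at most
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-magnitude loading entry positive per column
    coeffs = Vt.T
    for j in range(coeffs.shape[1]):
        i = int(np.argmax(np.abs(coeffs[:, j])))
        if coeffs[i, j] < 0:
            coeffs[:, j] *= -1.0
            U[:, j] *= -1.0
    var = s ** 2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    scores = Xc @ coeffs
    return ChemicalSpaceModel(
        column_means=means, coefficients=coeffs, explained_variance=frac,
        columns=columns, n_pcs_retained=min(n_pcs_retained, coeffs.shape[1]),
        training_scores=scores,
    )


def project(model: ChemicalSpaceModel, scaled_rows) -> np.ndarray:
    """Project scaled descriptor rows into PC space.

    ``scores = (rows - column_means) @ coefficients``. Rows must be scaled
    with the same ScalingParams as the training data.
    """
    X = np.asarray(scaled_rows, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.coefficients.shape[0]:
        raise ValueError(
            f"column mismatch: got {X.shape[1]}, model has {model.coefficients.shape[0]}")
    scores = (X - model.column_means) @ model.coefficients
    return scores[0] if single else scores


def hyperellipsoid(scores, coverage: float = 0.95, dims: int = 10) -> Hyperellipsoid:
    """Axis-aligned hyperellipsoid summarizing a score cloud.

    Per axis the diameter is the span between the (1-coverage)/2 and
    1-(1-coverage)/2 linear-interpolation quantiles (full range when
    coverage == 1). Center is the per-PC mean.
    """
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    if S.size == 0:
        raise ValueError("empty score set")
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must be in (0, 1]")
    if dims > S.shape[1]:
        raise ValueError(f"dims {dims} exceeds available PCs {S.shape[1]}")
    S = S[:, :dims]
    center = S.mean(axis=0)
    if coverage == 1.0:
        lo, hi = S.min(axis=0), S.max(axis=0)
    else:
        tail = (1.0 - coverage) / 2.0
        lo = np.quantile(S, tail, axis=0)
        hi = np.quantile(S, 1.0 - tail, axis=0)
    return Hyperellipsoid(center=center, ranges=hi - lo, coverage=coverage)


def _normalizer(universe: Hyperellipsoid, mode: str) -> float:
    if mode == "semi-axis":
        return universe.a_pc1
    if mode == "range":
        return float(universe.ranges[0])
    raise ValueError(f"unknown normalization mode {mode!r}")


def set_distance(set_a_scores, set_b_scores, universe: Hyperellipsoid,
                 dims: int = 10, mode: str = "semi-axis") -> tuple[float, float]:
    """Distance between two set centroids over the first *dims* PCs.

    Returns ``(normalized, raw)`` where normalized divides the Euclidean
    centroid distance by the universe's PC1 semi-axis (``mode="range"``
    uses the full PC1 range instead).
    """
    a = np.atleast_2d(np.asarray(set_a_scores, dtype=float))[:, :dims].mean(axis=0)
    b = np.atleast_2d(np.asarray(set_b_scores, dtype=float))[:, :dims].mean(axis=0)
    raw = float(np.linalg.norm(a - b))
    return raw / _normalizer(universe, mode), raw


def compound_distance(score_row, reference_set_scores, universe: Hyperellipsoid,
                      dims: int = 10, mode: str = "semi-axis") -> tuple[float, float]:
    """Distance of one compound's score row from a reference-set centroid."""
    x = np.asarray(score_row, dtype=float)[:dims]
    mu = np.atleast_2d(np.asarray(reference_set_scores, dtype=float))[:, :dims].mean(axis=0)
    raw = float(np.linalg.norm(x - mu))
    return raw / _normalizer(universe, mode), raw
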