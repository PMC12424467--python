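"""Standardization, PCA, and the symmetric grid over the score space.

PCA is computed from the singular value decomposition of the standardized
matrix (sample, n-1, variance convention). Sign convention: within each
loading column, the entry of largest magnitude is made positive, so results
are deterministic across platforms.

"Symmetric gridding" means the same number of equal-width bins on every
retained score axis, spanning the observed score range of that axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class ScalingModel:
    """Column means and sample standard deviations used for standardization."""

    means: np.ndarray
    sds: np.ndarray
    names: tuple[str, ...] | None = None


@dataclass(frozen=True)
class PCAModel:
    loadings: np.ndarray  # p x k, orthonormal columns
    explained_variance: np.ndarray  # k, descending
    explained_ratio: np.ndarray  # k, fractions of total variance


@dataclass(frozen=True)
class GridSpec:
    """Equal-width, equal-count binning of each of the k score axes."""

    k: int
    bins_per_axis: int
    edges: np.ndarray  # k x (bins_per_axis + 1), strictly increasing rows

    def centroid(self, cell: tuple[int, ...]) -> np.ndarray:
        """Geometric center of a cell."""
        return np.array(
            [(self.edges[a, c] + self.edges[a, c + 1]) / 2.0 for a, c in enumerate(cell)]
        )


def fit_scaling(X: np.ndarray, names: Sequence[str] | None = None) -> ScalingModel:
    """Column means/sds of X (n >= 2 rows); constant columns are rejected."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("scaling requires a 2-D matrix with at least 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0.0)
    if bad.size:
        labels = [names[i] if names is not None else f"column {i}" for i in bad]
        raise ValidationError(f"constant variable(s) cannot be scaled: {labels}")
    return ScalingModel(means=means, sds=sds, names=tuple(names) if names is not None else None)


def apply_scaling(X: np.ndarray, model: ScalingModel) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return (X - model.means) / model.sds


def fit_pca(Z: np.ndarray, k: int) -> PCAModel:
    """PCA of a standardized matrix via SVD, keeping k components.

    explained_variance are the per-component score variances (n-1 convention);
    explained_ratio divides by the total variance of Z, so the ratios over all
    components sum to 1.
    """
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    if k < 1 or k > p:
        raise ValidationError(f"k must be in [1, {p}], got {k}")
    _, S, Vt = np.linalg.svd(Z, full_matrices=False)
    tol = S.max(initial=0.0) * max(n, p) * np.finfo(float).eps
    rank = int((S > tol).sum())
    if k > rank:
        raise ValidationError(f"k={k} exceeds the rank ({rank}) of the data")
    total_variance = float((S**2).sum()) / (n - 1)
    loadings = Vt[:k].T.copy()
    # deterministic sign: largest-|entry| of each component made positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
    explained = S[:k] ** 2 / (n - 1)
    return PCAModel(
        loadings=loadings,
        explained_variance=explained,
        explained_ratio=explained / total_variance,
    )


def project(Z: np.ndarray, model: PCAModel) -> np.ndarray:
    """Scores = Z @ loadings (n x k)."""
    return np.asarray(Z, dtype=float) @ model.loadings


def build_grid(scores: np.ndarray, bins_per_axis: int) -> GridSpec:
    """Symmetric grid over the observed score range of each axis."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] == 0:
        raise ValidationError("scores must be a non-empty 2-D matrix")
    if bins_per_axis < 1:
        raise ValidationError("bins_per_axis must be >= 1")
    k = scores.shape[1]
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    span = hi - lo
    # degenerate axis (all scores equal): give it unit width so binning is defined
    span = np.where(span == 0.0, 1.0, span)
    # span*j/bins (in this order) keeps simple edges exactly representable
    edges = lo[:, None] + (span[:, None] * np.arange(bins_per_axis + 1)[None, :]) / bins_per_axis
    # pin the outer edges to the exact observed extrema (guards 1-ulp rounding)
    edges[:, 0] = lo
    edges[:, -1] = np.where(hi > lo, hi, edges[:, -1])
    return GridSpec(k=k, bins_per_axis=bins_per_axis, edges=edges)


def assign_cells(scores: np.ndarray, grid: GridSpec) -> tuple[np.ndarray, int]:
    """Cell ordinals for every score row, plus a count of out-of-range clamps.

    Points on an interior edge belong to the higher bin; points at the maximum
    edge belong to the last bin; out-of-range points (new data) are clamped to
    the nearest boundary bin and counted.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != grid.k:
        raise ValidationError(f"scores must have {grid.k} columns")
    lo = grid.edges[:, 0]
    hi = grid.edges[:, -1]
    # bin by the actual edges so containment is exact; interior edges -> higher bin
    raw = np.empty(scores.shape, dtype=int)
    for axis in range(grid.k):
        raw[:, axis] = np.searchsorted(grid.edges[axis], scores[:, axis], side="right") - 1
    clamped = int(np.any((scores < lo) | (scores > hi), axis=1).sum())
    cells = np.clip(raw, 0, grid.bins_per_axis - 1)
    return cells, clamped


def assign_cell(score_row: np.ndarray, grid: GridSpec) -> tuple[int, ...]:
    cells, _ = assign_cells(np.atleast_2d(score_row), grid)
    return tuple(int(c) for c in cells[0])


def model_to_dict(
    scaling: ScalingModel, pca: PCAModel, grid: GridSpec, feature_names: Sequence[str]
) -> dict:
    return {
        "feature_names": list(feature_names),
        "means": scaling.means.tolist(),
        "sds": scaling.sds.tolist(),
        "loadings": pca.loadings.tolist(),
        "explained_variance": pca.explained_variance.tolist(),
        "explained_ratio": pca.explained_ratio.tolist(),
        "grid": {
            "k": grid.k,
            "bins_per_axis": grid.bins_per_axis,
            "edges": grid.edges.tolist(),
        },
    }


def model_from_dict(doc: dict) -> tuple[ScalingModel, PCAModel, GridSpec, list[str]]:
    scaling = ScalingModel(
        means=np.array(doc["means"], dtype=float),
        sds=np.array(doc["sds"], dtype=float),
        names=tuple(doc["feature_names"]),
    )
    pca = PCAModel(
        loadings=np.array(doc["loadings"], dtype=float),
        explained_variance=np.array(doc["explained_variance"], dtype=float),
        explained_ratio=np.array(doc["explained_ratio"], dtype=float),
    )
    g = doc["grid"]
    grid = GridSpec(k=int(g["k"]), bins_per_axis=int(g["bins_per_axis"]), edges=np.array(g["edges"], dtype=float))
    return scaling, pca, grid, list(doc["feature_names"])


def save_model(path: str | Path, scaling: ScalingModel, pca: PCAModel, grid: GridSpec, feature_names: Sequence[str]) -> None:
    Path(path).write_text(json.dumps(model_to_dict(scaling, pca, grid, feature_names), indent=1))


def load_model(path: str | Path) -> tuple[ScalingModel, PCAModel, GridSpec, list[str]]:
    return model_from_dict(json.loads(Path(path).read_text()))
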