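"""Structure- and axis-space PCs and the tuned combined embedding.

Two low-dimensional views are combined: a "structure" PCA of the
per-batch-centered expression matrix over highly variable genes (the
batch centering stands in for mutual-nearest-neighbor correction at desk
scale) and an "axis" PCA of the cell-by-axis score matrix.  An
interpolation weight alpha scales the two blocks,

    combined(alpha) = [alpha * structure_pcs, (1 - alpha) * axis_pcs],

and is selected on a grid to maximize subtype separation plus batch
mixing, both measured by mean silhouette widths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import AnnotatedMatrix


def _pca(x: np.ndarray, n_pcs: int) -> np.ndarray:
    """Deterministic PCA scores via SVD with a fixed sign convention."""
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = min(n_pcs, rank)
    if k < n_pcs:
        warnings.warn(f"PCA rank {rank} below requested {n_pcs} components; reduced")
    for j in range(k):
        if vt[j, np.argmax(np.abs(vt[j]))] < 0:
            u[:, j] = -u[:, j]
    return u[:, :k] * s[:k]


def _unit_total_variance(pcs: np.ndarray) -> np.ndarray:
    total = pcs.var(axis=0).sum()
    if total <= 0:
        return pcs
    return pcs / np.sqrt(total)


def compute_pc_spaces(
    m: AnnotatedMatrix,
    axis_scores: pd.DataFrame,
    n_hvg: int = 3000,
    n_pcs: int = 30,
    batch_key: str = "sample",
) -> tuple[np.ndarray, np.ndarray]:
    """Batch-centered expression PCA and axis-score PCA, unit total variance.

    The axis space is capped at (number of axes - 1) components.
    """
    if m.lognorm is None:
        raise ValueError("compute_pc_spaces: log-normalized layer required")
    variances = m.lognorm.var(axis=0)
    k = min(n_hvg, m.n_genes)
    hvg = np.sort(np.argsort(variances, kind="stable")[::-1][:k])
    x = m.lognorm[:, hvg].copy()

    if batch_key in m.cell_meta.columns:
        batches = m.cell_meta[batch_key]
        for _, idx in batches.groupby(batches, observed=True, sort=False).indices.items():
            x[idx] -= x[idx].mean(axis=0)
    else:
        warnings.warn(f"compute_pc_spaces: no {batch_key!r} column; skipping batch centering")

    structure = _unit_total_variance(_pca(x, n_pcs))
    axis_cap = min(n_pcs, axis_scores.shape[1] - 1)
    axis = _unit_total_variance(_pca(axis_scores.to_numpy(dtype=float), axis_cap))
    return structure, axis


@dataclass
class TunedEmbedding:
    alpha: float
    combined_pcs: np.ndarray
    objective_curve: pd.DataFrame
    grid: list[float] = field(default_factory=list)


def _mean_silhouette(x: np.ndarray, labels: np.ndarray, seed: int, max_cells: int = 3000) -> float:
    from sklearn.metrics import silhouette_score

    if len(x) > max_cells:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(x), size=max_cells, replace=False))
        x, labels = x[idx], labels[idx]
        if len(np.unique(labels)) < 2:
            return np.nan
    return float(silhouette_score(x, labels, metric="euclidean"))


def combine_spaces(structure_pcs: np.ndarray, axis_pcs: np.ndarray, alpha: float) -> np.ndarray:
    return np.hstack([alpha * structure_pcs, (1.0 - alpha) * axis_pcs])


def tune_combined_embedding(
    structure_pcs: np.ndarray,
    axis_pcs: np.ndarray,
    subtype_labels,
    batch_labels,
    alpha_grid=None,
    k_neighbors: int = 30,
    seed: int = 0,
) -> TunedEmbedding:
    """Select the interpolation weight maximizing separation + mixing.

    separation(alpha) = mean silhouette over subtype labels;
    mixing(alpha) = 1 - mean silhouette over batch labels;
    ties on the objective resolve to the smaller alpha.  A term whose
    labels are constant is dropped with a warning.
    """
    if alpha_grid is None:
        alpha_grid = np.round(np.linspace(0.0, 1.0, 11), 10)
    alpha_grid = [float(a) for a in alpha_grid]
    if 0.0 not in alpha_grid or 1.0 not in alpha_grid:
        raise ValueError("alpha grid must include the endpoints 0 and 1")

    subtype_labels = np.asarray(subtype_labels)
    batch_labels = np.asarray(batch_labels)
    use_sep = len(np.unique(subtype_labels)) >= 2
    use_mix = len(np.unique(batch_labels)) >= 2
    if not use_sep:
        warnings.warn("tune_combined_embedding: single subtype; separation term dropped")
    if not use_mix:
        warnings.warn("tune_combined_embedding: single batch; mixing term dropped")
    if not use_sep and not use_mix:
        raise ValueError("tune_combined_embedding: no usable label set")

    records = []
    best_alpha, best_obj = None, -np.inf
    for alpha in alpha_grid:
        combined = combine_spaces(structure_pcs, axis_pcs, alpha)
        sep = _mean_silhouette(combined, subtype_labels, seed) if use_sep else np.nan
        mix = 1.0 - _mean_silhouette(combined, batch_labels, seed) if use_mix else np.nan
        obj = np.nansum([sep if use_sep else 0.0, mix if use_mix else 0.0])
        records.append({"alpha": alpha, "separation": sep, "mixing": mix, "objective": obj})
        if obj > best_obj + 1e-12:
            best_obj, best_alpha = obj, alpha

    curve = pd.DataFrame(records)
    return TunedEmbedding(
        alpha=best_alpha,
        combined_pcs=combine_spaces(structure_pcs, axis_pcs, best_alpha),
        objective_curve=curve,
        grid=alpha_grid,
    )


def kmeans_clusters(pcs: np.ndarray, n_clusters: int = 8, seed: int = 0) -> np.ndarray:
    """Simple k-means fallback producing cluster labels for synthetic runs."""
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(pcs)
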