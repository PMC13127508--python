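"""Bin-controlled gene-module scores and axis-based subtype assignment.

A module score for a cell is the mean log-normalized expression of the
module genes minus the mean over expression-matched control genes: genes
are binned by average expression across cells, and each module gene
contributes control genes sampled (with replacement) from its bin.  Axis
panels are competing module scores whose per-cell argmax assigns the
exocrine subtype, with the margin between the top two axes as confidence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import AnnotatedMatrix

DEFAULT_MARGIN_CUTS = (0.05, 0.15, 0.30)
CONFIDENCE_LABELS = ("very_low", "low", "moderate", "high")

#: default mapping of the eight scoring axes onto the seven subtype labels
DEFAULT_AXIS_TO_LABEL = {
    "acinar": "Acinar",
    "acinar_reg": "Acinar_REG+",
    "acinar_stress": "Acinar-stress",
    "ductal_core_1": "Ductal",
    "ductal_core_2": "Ductal",
    "ductal_cftr": "Ductal-CFTRhi",
    "ductal_muc5b": "Ductal-MUC5B",
    "ductal_injury": "Ductal-injury",
}


def expression_bins(lognorm: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each gene to one of ``n_bins`` equal-size bins by mean expression.

    Genes are ordered by average log-normalized expression (stable sort, so
    ties break by column position) and split into contiguous rank bins.
    """
    mean_expr = lognorm.mean(axis=0)
    order = np.argsort(mean_expr, kind="stable")
    bins = np.empty(lognorm.shape[1], dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins


def module_score(
    m: AnnotatedMatrix,
    genes: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell bin-controlled module score.

    Module genes absent from the matrix are dropped with a warning; an error
    is raised when none remain.  Control genes are drawn with replacement
    from each module gene's expression bin using ``seed``.
    """
    import warnings

    if m.lognorm is None:
        raise ValueError("module_score: log-normalized layer required")
    gene_index = m.genes
    present = [g for g in dict.fromkeys(genes) if g in gene_index]
    missing = [g for g in dict.fromkeys(genes) if g not in gene_index]
    if missing:
        warnings.warn(f"module_score: {len(missing)} module genes absent, e.g. {missing[:3]}")
    if not present:
        raise ValueError("module_score: no module gene present in the matrix")

    bins = expression_bins(m.lognorm, n_bins)
    positions = gene_index.get_indexer(present)
    rng = np.random.default_rng(seed)

    ctrl_cols: list[np.ndarray] = []
    for pos in positions:
        members = np.flatnonzero(bins == bins[pos])
        ctrl_cols.append(rng.choice(members, size=n_ctrl, replace=True))
    ctrl_pool = np.concatenate(ctrl_cols)

    module_mean = m.lognorm[:, positions].mean(axis=1)
    ctrl_mean = m.lognorm[:, ctrl_pool].mean(axis=1)
    return module_mean - ctrl_mean


def score_axes(
    m: AnnotatedMatrix,
    panels: "GeneSetCollection",
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell x axis score matrix from a collection of axis marker panels."""
    scores = {}
    for i, name in enumerate(panels.names):
        scores[name] = module_score(m, panels[name], n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + i)
    return pd.DataFrame(scores, index=m.cell_ids)


def assign_axis_subtype(
    scores: pd.DataFrame,
    axis_to_label: dict[str, str] | None = None,
    margin_cuts: tuple[float, float, float] = DEFAULT_MARGIN_CUTS,
) -> pd.DataFrame:
    """Assign each cell the label of its maximum-scoring axis.

    Ties break by the declared axis (column) order and are flagged.  The
    margin (top minus second score) maps onto four confidence buckets at
    the three ascending cut points.
    """
    if scores.shape[1] < 2:
        raise ValueError("assign_axis_subtype: need at least 2 axes")
    axis_to_label = dict(axis_to_label or DEFAULT_AXIS_TO_LABEL)
    for axis in scores.columns:
        if axis not in axis_to_label:
            raise ValueError(f"assign_axis_subtype: axis {axis!r} missing from label map")
    cuts = np.asarray(margin_cuts, dtype=float)
    if not np.all(np.diff(cuts) > 0):
        raise ValueError("margin_cuts must be strictly ascending")

    vals = scores.to_numpy(dtype=float)
    top_idx = np.argmax(vals, axis=1)  # first max wins ties
    top = vals[np.arange(len(vals)), top_idx]
    masked = vals.copy()
    masked[np.arange(len(vals)), top_idx] = -np.inf
    second = masked.max(axis=1)
    margin = top - second
    tie = margin == 0

    conf_idx = np.searchsorted(cuts, margin, side="right")
    axes = scores.columns.to_numpy()
    out = pd.DataFrame(
        {
            "axis": axes[top_idx],
            "subtype": [axis_to_label[a] for a in axes[top_idx]],
            "margin": margin,
            "confidence": [CONFIDENCE_LABELS[i] for i in conf_idx],
            "tie": tie,
        },
        index=scores.index,
    )
    return out
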