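"""Regulon-based TF activity inference and technical residualization.

A TF's activity in a cell summarizes the coordinated expression of its
regulon targets.  Per gene, log-normalized expression is z-scored across
cells; the activity is the weighted signed Stouffer combination

    activity = sum_t w_t * m_t * z_t / sqrt(sum_t w_t^2)

over targets present in the matrix (mode m in {-1, +1}, weight w > 0),
z-scaled per TF across cells.  TFs with fewer than ``min_regulon`` present
targets are skipped.  The residualization step regresses each TF's activity
on technical covariates (detected genes, %mito, %ribo, contamination, PC1
of the expression matrix) and keeps the re-scaled residuals as the primary
activity measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import AnnotatedMatrix, Regulon, N_GENES_DETECTED

RESIDUAL_COVARIATES = (N_GENES_DETECTED, "pct_mito", "pct_ribo", "contamination")


@dataclass
class ActivityMatrix:
    """Cells x TFs activity scores, z-scaled per TF."""

    values: pd.DataFrame
    residualized: bool = False
    covariates_used: list[str] = field(default_factory=list)
    degenerate_tfs: list[str] = field(default_factory=list)

    def __getitem__(self, tf: str) -> np.ndarray:
        return self.values[tf].to_numpy()


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    """Column z-score; (numerically) constant columns map to zero."""
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    scale = np.maximum(1.0, np.abs(x).max(axis=0, initial=0.0))
    out = np.zeros_like(x, dtype=float)
    ok = sd > 1e-12 * scale
    out[:, ok] = (x[:, ok] - mean[ok]) / sd[ok]
    return out


def infer_activity(m: AnnotatedMatrix, r: Regulon, min_regulon: int = 5) -> ActivityMatrix:
    """Score each TF's regulon against the log-normalized expression matrix."""
    if m.lognorm is None:
        raise ValueError("infer_activity: log-normalized layer required")
    r.validate()
    z = _zscore_columns(m.lognorm)
    gene_index = m.genes

    columns: dict[str, np.ndarray] = {}
    for tf in r.tfs:
        edges = r.targets_of(tf)
        present = edges[edges["target"].isin(gene_index)]
        if len(present) < min_regulon:
            warnings.warn(
                f"infer_activity: TF {tf!r} skipped "
                f"({len(present)} present targets < min_regulon={min_regulon})"
            )
            continue
        pos = gene_index.get_indexer(present["target"])
        w = present["weight"].to_numpy(dtype=float)
        mode = present["mode"].to_numpy(dtype=float)
        raw = z[:, pos] @ (w * mode) / np.sqrt(np.sum(w**2))
        columns[tf] = raw
    if not columns:
        raise ValueError("infer_activity: no TF passes the minimum regulon size")

    values = pd.DataFrame(columns, index=m.cell_ids)
    values = pd.DataFrame(
        _zscore_columns(values.to_numpy(dtype=float)), index=values.index, columns=values.columns
    )
    return ActivityMatrix(values=values)


def first_pc(lognorm: np.ndarray, n_hvg: int = 3000) -> np.ndarray:
    """First principal component score of the expression matrix over HVGs.

    Highly variable genes are the top ``n_hvg`` by variance (all genes when
    fewer).  The sign convention fixes the largest-|loading| gene positive,
    so results are reproducible across runs.
    """
    variances = lognorm.var(axis=0)
    k = min(n_hvg, lognorm.shape[1])
    hvg = np.sort(np.argsort(variances, kind="stable")[::-1][:k])
    x = lognorm[:, hvg] - lognorm[:, hvg].mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    loading = vt[0]
    if loading[np.argmax(np.abs(loading))] < 0:
        u[:, 0] = -u[:, 0]
    return u[:, 0] * s[0]


def residualize_activity(
    a: ActivityMatrix,
    meta: pd.DataFrame,
    pc1: np.ndarray,
    covariates: tuple[str, ...] = RESIDUAL_COVARIATES,
) -> ActivityMatrix:
    """OLS-residualize each TF's activity on technical covariates + PC1.

    Constant covariates are dropped with a warning; residuals are re-z-scaled
    per TF (an all-zero residual vector stays zero and flags the TF as
    degenerate).
    """
    n = len(a.values)
    cols = [np.ones(n)]
    used: list[str] = []
    for cov in covariates:
        if cov not in meta.columns:
            raise ValueError(f"residualize_activity: missing covariate {cov!r}")
        v = np.asarray(meta[cov], dtype=float)
        if np.any(~np.isfinite(v)):
            raise ValueError(f"residualize_activity: covariate {cov!r} has missing values")
        if np.ptp(v) == 0:
            warnings.warn(f"residualize_activity: constant covariate {cov!r} dropped")
            continue
        cols.append(v)
        used.append(cov)
    pc1 = np.asarray(pc1, dtype=float)
    if np.ptp(pc1) == 0:
        warnings.warn("residualize_activity: constant PC1 dropped")
    else:
        cols.append(pc1)
        used.append("PC1")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("residualize_activity: rank-deficient covariate design")

    Y = a.values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta

    degenerate = []
    sd = resid.std(axis=0)
    out = np.zeros_like(resid)
    for j, tf in enumerate(a.values.columns):
        if sd[j] > 1e-12:
            out[:, j] = (resid[:, j] - resid[:, j].mean()) / sd[j]
        else:
            degenerate.append(tf)
    values = pd.DataFrame(out, index=a.values.index, columns=a.values.columns)
    return ActivityMatrix(
        values=values, residualized=True, covariates_used=used, degenerate_tfs=degenerate
    )
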