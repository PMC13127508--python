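"""Adaptive and fixed-threshold cell filtering.

Two presets mirror the two analysis arms: the exocrine (snRNA-seq) arm uses
per-sample MAD trimming on detected genes plus fixed upper bounds (min 150
genes, <10% mitochondrial, <35% ribosomal, contamination <0.5); the tumor
(scRNA-seq) arm uses fixed bounds only (min 500 genes, <25% mitochondrial,
<20% ribosomal, contamination <0.5).  Keep requires strictly-less-than each
upper percentage threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import AnnotatedMatrix, GeneSetCollection, N_GENES_DETECTED

#: consistency constant making the MAD estimate the normal SD
MAD_SCALE = 1.4826


@dataclass
class QCThresholds:
    mad_k: float = 3.0
    min_genes: int = 150
    max_pct_mito: float = 10.0
    max_pct_ribo: float = 35.0
    max_contamination: float = 0.5
    use_mad_on_genes: bool = True
    per_sample: bool = True

    @classmethod
    def exocrine(cls) -> "QCThresholds":
        return cls()

    @classmethod
    def tumor(cls) -> "QCThresholds":
        return cls(
            min_genes=500,
            max_pct_mito=25.0,
            max_pct_ribo=20.0,
            max_contamination=0.5,
            use_mad_on_genes=False,
            per_sample=False,
        )


PRESETS = {"exocrine": QCThresholds.exocrine, "tumor": QCThresholds.tumor}


def mad_bounds(x, k: float) -> tuple[float, float]:
    """median(x) +/- k * 1.4826 * median(|x - median(x)|)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("mad_bounds: empty vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("mad_bounds: non-finite values")
    med = float(np.median(x))
    spread = k * MAD_SCALE * float(np.median(np.abs(x - med)))
    return med - spread, med + spread


def apply_qc_filter(
    m: AnnotatedMatrix, t: QCThresholds
) -> tuple[AnnotatedMatrix, pd.Series]:
    """Keep cells passing ALL active criteria; report per-criterion removals.

    The removal report double-counts cells failing several criteria;
    ``total_removed`` is the distinct count.
    """
    meta = m.cell_meta
    required = ["pct_mito", "pct_ribo", "contamination"]
    if t.use_mad_on_genes and t.per_sample:
        required.append("sample")
    for col in required:
        if col not in meta.columns:
            raise ValueError(f"apply_qc_filter: missing metadata column {col!r}")

    n_genes = np.asarray(meta[N_GENES_DETECTED], dtype=float)
    keep = np.ones(m.n_cells, dtype=bool)
    report: dict[str, int] = {}

    if t.use_mad_on_genes:
        within = np.ones(m.n_cells, dtype=bool)
        if t.per_sample:
            for _, idx in meta.groupby("sample", observed=True, sort=False).indices.items():
                lo, hi = mad_bounds(n_genes[idx], t.mad_k)
                within[idx] = (n_genes[idx] >= lo) & (n_genes[idx] <= hi)
        else:
            lo, hi = mad_bounds(n_genes, t.mad_k)
            within = (n_genes >= lo) & (n_genes <= hi)
        report["mad_genes"] = int((~within).sum())
        keep &= within

    fails_min = n_genes < t.min_genes
    report["min_genes"] = int(fails_min.sum())
    keep &= ~fails_min

    for col, bound, name in (
        ("pct_mito", t.max_pct_mito, "pct_mito"),
        ("pct_ribo", t.max_pct_ribo, "pct_ribo"),
        ("contamination", t.max_contamination, "contamination"),
    ):
        vals = np.asarray(meta[col], dtype=float)
        fails = ~(vals < bound)
        report[name] = int(fails.sum())
        keep &= ~fails

    report["total_removed"] = int((~keep).sum())
    kept = m.subset_cells(keep)
    return kept, pd.Series(report, name="removed")


def select_exocrine(
    m: AnnotatedMatrix,
    acinar_panel: list[str],
    ductal_panel: list[str],
    exclusion_panels: GeneSetCollection | None,
    score_margin: float = 0.0,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> AnnotatedMatrix:
    """Retain clusters whose exocrine module score dominates exclusion panels.

    Per cluster, the exocrine score is the larger of the mean acinar-panel
    and mean ductal-panel module scores; the cluster is kept when it exceeds
    the maximal exclusion-panel mean score (0 when no exclusion panels) by
    at least ``score_margin``.
    """
    from .scoring import module_score

    if "cluster" not in m.cell_meta.columns:
        raise ValueError("select_exocrine: 'cluster' metadata column required")
    if not acinar_panel or not ductal_panel:
        raise ValueError("select_exocrine: marker panels must be non-empty")

    acinar = module_score(m, acinar_panel, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    ductal = module_score(m, ductal_panel, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + 1)
    excl_scores = []
    if exclusion_panels is not None:
        for i, name in enumerate(exclusion_panels.names):
            excl_scores.append(
                module_score(m, exclusion_panels[name], n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + 2 + i)
            )

    clusters = m.cell_meta["cluster"]
    keep_clusters = []
    for cl, idx in clusters.groupby(clusters, observed=True, sort=False).indices.items():
        exo = max(float(np.mean(acinar[idx])), float(np.mean(ductal[idx])))
        excl = max((float(np.mean(s[idx])) for s in excl_scores), default=0.0)
        if exo - excl >= score_margin:
            keep_clusters.append(cl)
    if not keep_clusters:
        raise ValueError("select_exocrine: no cluster passes the score margin")
    mask = clusters.isin(keep_clusters).to_numpy()
    return m.subset_cells(mask)
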