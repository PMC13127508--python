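"""NMF-signature scoring and the three-family tumor-cell classifier.

Four signature gene sets (Sig1, Sig2, Sig6, Sig10) span the
Classical-Basal transcriptional continuum of pancreatic tumor cells.
Per cell, each signature scores as the mean log-normalized expression of
its genes (intersected with the expressed gene universe); the classical
and basal fractions are

    p_classical = (Sig1 + Sig6) / total,   p_basal = (Sig2 + Sig10) / total,

with total the sum over all four scores.  Families follow explicit
thresholds applied in order: Classical if p_classical >= 0.60 and
p_basal <= 0.30; Basal if p_basal >= 0.60 and p_classical <= 0.30;
Hybrid if both are at least 0.30; otherwise Unassigned.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import AnnotatedMatrix, GeneSetCollection

SIGNATURES = ("Sig1", "Sig2", "Sig6", "Sig10")
CLASSICAL_SIGS = ("Sig1", "Sig6")
BASAL_SIGS = ("Sig2", "Sig10")

FAMILIES = ("Classical", "Hybrid", "Basal", "Unassigned")


def classify_family(p_classical: float, p_basal: float) -> str:
    """Apply the family thresholds with Classical -> Basal -> Hybrid precedence."""
    if p_classical is None or p_basal is None:
        return "Unassigned"
    if np.isnan(p_classical) or np.isnan(p_basal):
        return "Unassigned"
    if not (0 <= p_classical <= 1 and 0 <= p_basal <= 1):
        raise ValueError("classify_family: fractions must lie in [0, 1]")
    if p_classical >= 0.60 and p_basal <= 0.30:
        return "Classical"
    if p_basal >= 0.60 and p_classical <= 0.30:
        return "Basal"
    if p_classical >= 0.30 and p_basal >= 0.30:
        return "Hybrid"
    return "Unassigned"


def score_signatures(m: AnnotatedMatrix, sigs: GeneSetCollection) -> pd.DataFrame:
    """Per-cell FamilyCall table: signature scores, fractions, and family.

    Each signature must retain at least one gene after intersection with
    the matrix's genes; cells with zero total signal get missing fractions
    and family Unassigned.
    """
    if m.lognorm is None:
        raise ValueError("score_signatures: log-normalized layer required")
    missing_sets = [s for s in SIGNATURES if s not in sigs.sets]
    if missing_sets:
        raise ValueError(f"score_signatures: collection missing signatures {missing_sets}")

    scores = {}
    for name in SIGNATURES:
        present = [g for g in sigs[name] if g in m.genes]
        if not present:
            raise ValueError(f"score_signatures: signature {name!r} has no genes in the matrix")
        pos = m.genes.get_indexer(present)
        scores[name] = m.lognorm[:, pos].mean(axis=1)

    frame = pd.DataFrame(scores, index=m.cell_ids)
    total = frame[list(SIGNATURES)].sum(axis=1)
    classical = frame[list(CLASSICAL_SIGS)].sum(axis=1)
    basal = frame[list(BASAL_SIGS)].sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        p_classical = np.where(total > 0, classical / total, np.nan)
        p_basal = np.where(total > 0, basal / total, np.nan)
    frame["p_classical"] = p_classical
    frame["p_basal"] = p_basal
    frame["family"] = [
        classify_family(pc, pb) for pc, pb in zip(frame["p_classical"], frame["p_basal"])
    ]
    return frame


def family_activity_summary(calls: pd.DataFrame, activity: np.ndarray) -> pd.DataFrame:
    """Mean/SD of an activity vector stratified by assigned family."""
    activity = np.asarray(activity, dtype=float)
    rows = []
    for fam in FAMILIES:
        mask = (calls["family"] == fam).to_numpy()
        if mask.any():
            rows.append(
                {
                    "family": fam,
                    "n_cells": int(mask.sum()),
                    "activity_mean": float(activity[mask].mean()),
                    "activity_sd": float(activity[mask].std()),
                }
            )
    return pd.DataFrame(rows)
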