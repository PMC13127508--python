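"""Core in-memory containers for the pipeline.

The central container is :class:`AnnotatedMatrix`, a cells x genes count
matrix with an optional log-normalized layer and per-cell / per-gene
metadata tables.  Regulatory networks are :class:`Regulon` objects (signed,
weighted TF->target edges) and marker panels / gene modules / tumor
signatures are :class:`GeneSetCollection` objects.

Conventions: cells are rows, genes are columns; gene identity is the
(case-sensitive) symbol string; the log-normalized layer is the natural log
of scaled counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an on-disk input violates its format contract."""


#: metadata columns every per-cell table is expected to carry once populated
CELL_META_COLUMNS = (
    "donor",
    "context",
    "sample",
    "pct_mito",
    "pct_ribo",
    "contamination",
)

#: per-cell number of genes with nonzero counts ("cngeneson" in model formulas)
N_GENES_DETECTED = "n_genes_detected"


@dataclass
class AnnotatedMatrix:
    """Cells x genes counts with optional log-normalized layer and metadata.

    Parameters
    ----------
    counts
        Non-negative integer array, shape (n_cells, n_genes).
    cell_meta
        DataFrame indexed by unique cell id.  Always carries
        ``n_genes_detected``; pipeline metadata columns (donor, context,
        sample, pct_mito, pct_ribo, contamination, cluster, subtype) are
        added as they become available.
    gene_meta
        DataFrame indexed by unique gene symbol.
    lognorm
        Natural-log of library-scaled counts, same shape as ``counts``,
        or None before normalization.
    """

    counts: np.ndarray
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    lognorm: np.ndarray | None = None

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    @property
    def genes(self) -> pd.Index:
        return self.gene_meta.index

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check container invariants; raise ``ValueError`` on violation."""
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        if self.counts.shape != (len(self.cell_meta), len(self.gene_meta)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match metadata "
                f"({len(self.cell_meta)} cells, {len(self.gene_meta)} genes)"
            )
        if not self.cell_meta.index.is_unique:
            raise ValueError("cell ids are not unique")
        if not self.gene_meta.index.is_unique:
            raise ValueError("gene symbols are not unique")
        if np.any(self.counts < 0):
            raise ValueError("counts contain negative entries")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts contain non-integer entries")
        detected = (self.counts > 0).sum(axis=1)
        if N_GENES_DETECTED in self.cell_meta.columns:
            if not np.array_equal(
                np.asarray(self.cell_meta[N_GENES_DETECTED], dtype=int), detected
            ):
                raise ValueError("n_genes_detected inconsistent with counts")
        if self.lognorm is not None:
            if self.lognorm.shape != self.counts.shape:
                raise ValueError("lognorm shape differs from counts")
            if np.any((self.lognorm == 0) != (self.counts == 0)):
                raise ValueError("lognorm zero pattern differs from counts")

    # ------------------------------------------------------------------
    def subset_cells(self, mask_or_ids) -> "AnnotatedMatrix":
        """Return a new matrix restricted to the given cells (mask or ids)."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray, list)) and np.asarray(
            mask_or_ids
        ).dtype == bool:
            mask = np.asarray(mask_or_ids, dtype=bool)
            idx = np.flatnonzero(mask)
        else:
            idx = self.cell_meta.index.get_indexer(pd.Index(mask_or_ids))
            if np.any(idx < 0):
                raise KeyError("unknown cell ids in subset request")
        return AnnotatedMatrix(
            counts=self.counts[idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
            gene_meta=self.gene_meta.copy(),
            lognorm=None if self.lognorm is None else self.lognorm[idx],
        )

    def copy(self) -> "AnnotatedMatrix":
        return AnnotatedMatrix(
            counts=self.counts.copy(),
            cell_meta=self.cell_meta.copy(),
            gene_meta=self.gene_meta.copy(),
            lognorm=None if self.lognorm is None else self.lognorm.copy(),
        )

    def to_anndata(self):
        """Export to :class:`anndata.AnnData` (X = lognorm, counts as layer)."""
        import anndata as ad

        X = self.lognorm if self.lognorm is not None else self.counts.astype(float)
        adata = ad.AnnData(
            X=X.copy(),
            obs=self.cell_meta.copy(),
            var=self.gene_meta.copy(),
            layers={"counts": self.counts.copy()},
        )
        return adata


def make_annotated(
    counts: np.ndarray,
    cell_ids: Sequence[str],
    genes: Sequence[str],
    cell_meta: pd.DataFrame | None = None,
) -> AnnotatedMatrix:
    """Assemble an :class:`AnnotatedMatrix`, computing ``n_genes_detected``."""
    counts = np.asarray(counts)
    meta = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    if cell_meta is not None:
        meta = cell_meta.copy()
        meta.index = pd.Index(cell_ids, name="cell_id")
    meta[N_GENES_DETECTED] = (counts > 0).sum(axis=1).astype(int)
    gmeta = pd.DataFrame(index=pd.Index(genes, name="gene"))
    m = AnnotatedMatrix(counts=counts, cell_meta=meta, gene_meta=gmeta)
    m.validate()
    return m


def log_normalize(m: AnnotatedMatrix, scale_factor: float = 10_000.0) -> AnnotatedMatrix:
    """Fill the log-normalized layer: ln(1 + count / cell_total * scale_factor).

    Cells with zero total counts must have been removed by QC first; they
    raise an error naming the offending cell id.
    """
    totals = m.counts.sum(axis=1).astype(float)
    if np.any(totals == 0):
        bad = m.cell_ids[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total counts; remove it before normalizing")
    lognorm = np.log1p(m.counts / totals[:, None] * scale_factor)
    out = replace(m, lognorm=lognorm)
    out.validate()
    return out


# ----------------------------------------------------------------------
@dataclass
class Regulon:
    """Signed, weighted TF -> target edges.

    ``edges`` has columns tf, target, mode (+1 activation / -1 repression)
    and weight (> 0).  (tf, target) pairs are unique.
    """

    edges: pd.DataFrame

    def __post_init__(self):
        required = ["tf", "target", "mode", "weight"]
        if list(self.edges.columns[:4]) != required:
            self.edges = self.edges[required]
        self.edges = self.edges.reset_index(drop=True)

    def validate(self) -> None:
        e = self.edges
        if e.duplicated(subset=["tf", "target"]).any():
            raise ValueError("duplicate (tf, target) pairs in regulon")
        if not set(np.unique(e["mode"])) <= {-1, 1}:
            raise FormatError("regulon mode values must be -1 or +1")
        w = np.asarray(e["weight"], dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("regulon weights must be finite and positive")

    @property
    def tfs(self) -> list[str]:
        return list(pd.unique(self.edges["tf"]))

    def targets_of(self, tf: str) -> pd.DataFrame:
        return self.edges[self.edges["tf"] == tf]

    def merge(self, other: "Regulon") -> "Regulon":
        """Union of two collections; self wins (tf, target) conflicts."""
        combined = pd.concat([self.edges, other.edges], ignore_index=True)
        combined = combined.drop_duplicates(subset=["tf", "target"], keep="first")
        out = Regulon(combined.reset_index(drop=True))
        out.validate()
        return out


@dataclass
class GeneSetCollection:
    """Named gene sets with a role tag.

    ``kind`` distinguishes axis marker panels, curated gene modules, and
    tumor NMF signatures; the structure is identical.
    """

    sets: dict[str, list[str]]
    kind: str = "gene_module"

    KINDS = ("axis_panel", "gene_module", "nmf_signature")

    def validate(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown gene-set kind {self.kind!r}")
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise FormatError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)


def deduplicate_genes(name: str, genes: Iterable[str]) -> list[str]:
    """Drop within-set duplicates preserving order; warn when any found."""
    seen: dict[str, None] = {}
    dups = []
    for g in genes:
        if g in seen:
            dups.append(g)
        else:
            seen[g] = None
    if dups:
        warnings.warn(f"gene set {name!r}: dropped duplicate genes {sorted(set(dups))}")
    return list(seen)
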