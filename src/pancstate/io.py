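"""Readers and writers for the standard on-disk formats.

Counts travel as MatrixMarket coordinate files with one-entry-per-line
gene and barcode TSVs (10x convention: genes x cells on disk, 1-based
indices; orientation is auto-detected on read).  Gene sets use GMT, regulons
a 4-column TSV, and cell metadata a TSV keyed by ``cell_id``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datamodel import (
    AnnotatedMatrix,
    FormatError,
    GeneSetCollection,
    Regulon,
    deduplicate_genes,
    make_annotated,
)

REQUIRED_META_COLUMNS = (
    "cell_id",
    "donor",
    "context",
    "sample",
    "pct_mito",
    "pct_ribo",
    "contamination",
)


def _read_lines(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts_mtx(matrix_path, genes_path, barcodes_path) -> AnnotatedMatrix:
    """Read a MatrixMarket coordinate counts file with gene/barcode labels.

    Orientation is detected by matching the matrix dimensions against the
    label file lengths; square matrices default to the on-disk 10x
    convention (genes as rows).  Output is always cells x genes.
    """
    genes = _read_lines(genes_path)
    barcodes = _read_lines(barcodes_path)
    mat = scipy.io.mmread(str(matrix_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    n_rows, n_cols = mat.shape
    if n_rows == len(genes) and n_cols == len(barcodes):
        counts = mat.T
    elif n_rows == len(barcodes) and n_cols == len(genes):
        counts = mat
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither (genes={len(genes)}, "
            f"barcodes={len(barcodes)}) orientation"
        )
    if np.any(counts < 0):
        raise FormatError("count matrix contains negative entries")
    if not np.allclose(counts, np.round(counts)):
        raise FormatError("count matrix contains non-integer entries")
    return make_annotated(counts.astype(np.int64), barcodes, genes)


def write_counts_mtx(m: AnnotatedMatrix, matrix_path, genes_path, barcodes_path) -> None:
    """Write counts in the on-disk convention (genes x cells) plus labels."""
    sparse = scipy.sparse.coo_matrix(m.counts.T)
    scipy.io.mmwrite(str(matrix_path), sparse, field="integer")
    Path(genes_path).write_text("".join(f"{g}\n" for g in m.genes))
    Path(barcodes_path).write_text("".join(f"{c}\n" for c in m.cell_ids))


def read_cell_meta(path) -> pd.DataFrame:
    """Read the per-cell metadata TSV; requires the standard columns."""
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"cell metadata missing required columns: {missing}")
    meta = meta.set_index("cell_id")
    if not meta.index.is_unique:
        raise FormatError("cell metadata contains duplicate cell ids")
    return meta


def attach_cell_meta(m: AnnotatedMatrix, meta: pd.DataFrame) -> AnnotatedMatrix:
    """Join metadata columns onto the matrix's cell table (ids must match)."""
    if not m.cell_ids.isin(meta.index).all():
        missing = m.cell_ids[~m.cell_ids.isin(meta.index)][:5].tolist()
        raise FormatError(f"metadata missing cells, e.g. {missing}")
    joined = m.cell_meta.join(meta.loc[m.cell_ids], how="left", rsuffix="_meta")
    out = AnnotatedMatrix(m.counts, joined, m.gene_meta, m.lognorm)
    out.validate()
    return out


# ----------------------------------------------------------------------
def read_gene_sets(path, kind: str = "gene_module") -> GeneSetCollection:
    """Parse a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has no genes")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = deduplicate_genes(name, genes)
    coll = GeneSetCollection(sets=sets, kind=kind)
    coll.validate()
    return coll


def write_gene_sets(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_regulon(path) -> Regulon:
    """Parse a 4-column regulon TSV (tf, target, mode, weight; header required)."""
    table = pd.read_csv(path, sep="\t")
    required = ["tf", "target", "mode", "weight"]
    if list(table.columns[:4]) != required:
        raise FormatError(f"regulon TSV must have header columns {required}")
    if not set(np.unique(table["mode"])) <= {-1, 1}:
        raise FormatError("regulon mode values must be -1 or +1")
    n_before = len(table)
    table = table.drop_duplicates(subset=["tf", "target"], keep="first")
    if len(table) < n_before:
        warnings.warn(f"regulon {path}: dropped {n_before - len(table)} duplicate edges")
    reg = Regulon(table.reset_index(drop=True))
    reg.validate()
    return reg


def write_regulon(r: Regulon, path) -> None:
    r.edges.to_csv(path, sep="\t", index=False)
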