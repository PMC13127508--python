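"""Container invariants and on-disk format round trips."""

import math

import numpy as np
import pandas as pd
import pytest

import pancstate as ps
from pancstate import io as psio
from pancstate.datamodel import FormatError


def _write_mtx(tmp_path, lines, genes, barcodes):
    mtx = tmp_path / "matrix.mtx"
    mtx.write_text("%%MatrixMarket matrix coordinate integer general\n" + lines)
    gpath = tmp_path / "genes.tsv"
    gpath.write_text("".join(f"{g}\n" for g in genes))
    bpath = tmp_path / "barcodes.tsv"
    bpath.write_text("".join(f"{b}\n" for b in barcodes))
    return mtx, gpath, bpath


class TestReadCountsMtx:
    def test_direct_transcription(self, tmp_path):
        # genes x cells on disk: 3 genes, 2 cells, entries (1,1)=4, (3,2)=1
        paths = _write_mtx(tmp_path, "3 2 2\n1 1 4\n3 2 1\n", ["ga", "gb", "gc"], ["c1", "c2"])
        m = psio.read_counts_mtx(*paths)
        np.testing.assert_array_equal(m.counts, [[4, 0, 0], [0, 0, 1]])
        np.testing.assert_array_equal(m.cell_meta["n_genes_detected"], [1, 1])

    def test_empty_coordinate_list(self, tmp_path):
        paths = _write_mtx(tmp_path, "2 2 0\n", ["ga", "gb"], ["c1", "c2"])
        m = psio.read_counts_mtx(*paths)
        assert m.counts.sum() == 0
        np.testing.assert_array_equal(m.cell_meta["n_genes_detected"], [0, 0])

    def test_orientation_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 5, size=(4, 7))
        m = ps.make_annotated(counts, [f"c{i}" for i in range(4)], [f"g{i}" for i in range(7)])
        paths = (tmp_path / "m.mtx", tmp_path / "g.tsv", tmp_path / "b.tsv")
        psio.write_counts_mtx(m, *paths)
        back = psio.read_counts_mtx(*paths)
        np.testing.assert_array_equal(back.counts, m.counts)
        assert list(back.genes) == list(m.genes)
        assert list(back.cell_ids) == list(m.cell_ids)

    def test_dimension_mismatch_raises(self, tmp_path):
        paths = _write_mtx(tmp_path, "3 2 1\n1 1 4\n", ["ga", "gb", "gc", "gd"], ["c1", "c2", "c3"])
        with pytest.raises(FormatError):
            psio.read_counts_mtx(*paths)

    def test_negative_entries_raise(self, tmp_path):
        paths = _write_mtx(tmp_path, "2 2 1\n1 1 -3\n", ["ga", "gb"], ["c1", "c2"])
        with pytest.raises(FormatError):
            psio.read_counts_mtx(*paths)


class TestLogNormalize:
    def test_closed_form(self):
        m = ps.make_annotated(np.array([[1, 1]]), ["c1"], ["ga", "gb"])
        out = ps.log_normalize(m, scale_factor=10_000)
        assert out.lognorm == pytest.approx(
            np.full((1, 2), math.log(1 + 5000)), abs=1e-6
        )
        assert out.lognorm[0, 0] == pytest.approx(8.517393, abs=1e-6)

    def test_zero_maps_to_zero_and_monotone(self):
        m = ps.make_annotated(np.array([[0, 1, 3]]), ["c1"], ["ga", "gb", "gc"])
        out = ps.log_normalize(m)
        assert out.lognorm[0, 0] == 0.0
        assert out.lognorm[0, 1] < out.lognorm[0, 2]

    def test_scale_invariance_of_proportions(self):
        m1 = ps.make_annotated(np.array([[2, 6]]), ["c1"], ["ga", "gb"])
        m2 = ps.make_annotated(np.array([[4, 12]]), ["c1"], ["ga", "gb"])
        np.testing.assert_allclose(
            ps.log_normalize(m1).lognorm, ps.log_normalize(m2).lognorm
        )

    def test_zero_total_cell_names_culprit(self):
        m = ps.make_annotated(np.array([[1, 0], [0, 0]]), ["good", "empty"], ["ga", "gb"])
        with pytest.raises(ValueError, match="empty"):
            ps.log_normalize(m)


class TestGeneSets:
    def test_gmt_parse(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("ductal_core\tna\tKRT19\tMUC1\tEPCAM\n")
        coll = psio.read_gene_sets(path, kind="gene_module")
        assert coll["ductal_core"] == ["KRT19", "MUC1", "EPCAM"]

    def test_duplicates_dropped_with_warning(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("s1\tna\tA\tB\tA\n")
        with pytest.warns(UserWarning, match="duplicate"):
            coll = psio.read_gene_sets(path)
        assert coll["s1"] == ["A", "B"]

    def test_empty_set_raises(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("s1\tna\t\n")
        with pytest.raises(FormatError):
            psio.read_gene_sets(path)

    def test_round_trip(self, tmp_path):
        coll = ps.GeneSetCollection({"a": ["X", "Y"], "b": ["Z"]}, kind="axis_panel")
        psio.write_gene_sets(coll, tmp_path / "x.gmt")
        back = psio.read_gene_sets(tmp_path / "x.gmt", kind="axis_panel")
        assert back.sets == coll.sets


class TestRegulonIO:
    def test_parse_single_edge(self, tmp_path):
        path = tmp_path / "reg.tsv"
        path.write_text("tf\ttarget\tmode\tweight\nPDX1\tINS\t1\t1.0\n")
        reg = psio.read_regulon(path)
        assert len(reg.edges) == 1
        assert reg.edges.loc[0, "mode"] == 1

    def test_duplicate_edges_deduplicated(self, tmp_path):
        path = tmp_path / "reg.tsv"
        path.write_text(
            "tf\ttarget\tmode\tweight\nPDX1\tINS\t1\t1.0\nPDX1\tINS\t1\t2.0\n"
        )
        with pytest.warns(UserWarning, match="duplicate"):
            reg = psio.read_regulon(path)
        assert len(reg.edges) == 1
        assert reg.edges.loc[0, "weight"] == 1.0  # first wins

    def test_bad_mode_raises(self, tmp_path):
        path = tmp_path / "reg.tsv"
        path.write_text("tf\ttarget\tmode\tweight\nPDX1\tINS\t2\t1.0\n")
        with pytest.raises(FormatError):
            psio.read_regulon(path)

    def test_round_trip(self, tmp_path):
        edges = pd.DataFrame(
            {"tf": ["T", "T"], "target": ["A", "B"], "mode": [1, -1], "weight": [1.0, 0.5]}
        )
        reg = ps.Regulon(edges)
        psio.write_regulon(reg, tmp_path / "r.tsv")
        back = psio.read_regulon(tmp_path / "r.tsv")
        pd.testing.assert_frame_equal(back.edges, reg.edges)

    def test_merge_first_collection_wins(self):
        a = ps.Regulon(pd.DataFrame({"tf": ["T"], "target": ["A"], "mode": [1], "weight": [1.0]}))
        b = ps.Regulon(
            pd.DataFrame(
                {"tf": ["T", "T"], "target": ["A", "B"], "mode": [-1, 1], "weight": [2.0, 1.0]}
            )
        )
        merged = a.merge(b)
        assert len(merged.edges) == 2
        row = merged.edges.set_index("target").loc["A"]
        assert row["mode"] == 1 and row["weight"] == 1.0


def test_validate_catches_inconsistencies():
    counts = np.array([[1, 0], [2, 3]])
    m = ps.make_annotated(counts, ["c1", "c2"], ["g1", "g2"])
    m.cell_meta.loc["c1", "n_genes_detected"] = 5
    with pytest.raises(ValueError, match="n_genes_detected"):
        m.validate()
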