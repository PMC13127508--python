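"""Two-part hurdle fits, evidence combination, BH FDR, and rank export."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pancstate as ps
from pancstate.hurdle import (
    STATUS_DEGENERATE,
    STATUS_OK,
    STATUS_TOO_FEW,
    HurdleModel,
    read_rank_file,
)
from pancstate.simulate import generate_hurdle_genes


class TestFitHurdleGene:
    def test_too_few_positive(self):
        rng = np.random.default_rng(0)
        expr = np.zeros(500)
        expr[:24] = rng.uniform(1, 3, 24)
        res = ps.fit_hurdle_gene(expr, rng.normal(size=500))
        assert res.status == STATUS_TOO_FEW
        assert res.n_pos == 24
        assert np.isnan(res.p_det) and np.isnan(res.p_cont)

    def test_all_detected_is_degenerate_with_continuous_fit(self):
        rng = np.random.default_rng(1)
        act = rng.normal(size=300)
        expr = 2.0 + 0.5 * act + rng.normal(0, 0.3, 300)
        expr = np.maximum(expr, 0.01)
        res = ps.fit_hurdle_gene(expr, act)
        assert res.status == STATUS_DEGENERATE
        assert np.isnan(res.logOR_det)
        assert res.beta_cont == pytest.approx(0.5, abs=0.1)
        # single-component combination passes the continuous stats through
        assert res.p_combined == pytest.approx(res.p_cont)

    def test_recovers_planted_detection_effect(self):
        expr, act, meta, _ = generate_hurdle_genes(
            n_cells=2000, n_genes=1, logOR_det=1.0, seed=5
        )
        res = ps.fit_hurdle_gene(expr[:, 0], act, meta)
        assert res.status == STATUS_OK
        assert res.logOR_det == pytest.approx(1.0, abs=0.3)
        assert res.OR_det == pytest.approx(np.exp(res.logOR_det))
        assert np.sign(res.z_det) == np.sign(res.logOR_det)

    def test_continuous_component_matches_lstsq(self):
        rng = np.random.default_rng(7)
        act = rng.normal(size=400)
        expr = np.maximum(1.5 + 0.3 * act + rng.normal(0, 0.4, 400), 0.01)
        expr[rng.choice(400, 100, replace=False)] = 0.0
        res = ps.fit_hurdle_gene(expr, act)
        pos = expr > 0
        X = np.column_stack([np.ones(pos.sum()), act[pos]])
        beta = np.linalg.lstsq(X, expr[pos], rcond=None)[0]
        assert res.beta_cont == pytest.approx(beta[1], abs=1e-8)


class TestCombineEvidence:
    def test_null_inputs_give_null_output(self):
        z, p = ps.combine_evidence(1.0, 1.0, 1.0, 1.0)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_equal_weight_closed_form(self):
        p2 = 2 * stats.norm.sf(2)  # p-value whose signed z is exactly 2
        z, _ = ps.combine_evidence(p2, 1.0, p2, 1.0, weights=(1.0, 1.0))
        assert z == pytest.approx(2.828427, abs=1e-6)

    def test_two_to_one_weight_closed_form(self):
        p2 = 2 * stats.norm.sf(2)
        z, _ = ps.combine_evidence(p2, 1.0, p2, 1.0, weights=(2.0, 1.0))
        assert z == pytest.approx(2.683282, abs=1e-6)

    def test_fisher_closed_form(self):
        _, p = ps.combine_evidence(0.5, 1.0, 0.5, -1.0)
        assert p == pytest.approx(0.5965736, abs=1e-6)

    def test_clipping(self):
        z, _ = ps.combine_evidence(1e-300, 1.0, 1e-300, 1.0, clip=10.0)
        assert z == pytest.approx((10 + 10) / np.sqrt(2))

    def test_single_component_passthrough(self):
        z, p = ps.combine_evidence(0.04, -1.0, None, 1.0)
        assert p == 0.04
        assert z == pytest.approx(-stats.norm.isf(0.02))
        assert ps.combine_evidence(None, 1.0, None, 1.0) == (pytest.approx(np.nan, nan_ok=True),) * 2

    def test_symmetric_under_component_swap(self):
        z1, p1 = ps.combine_evidence(0.01, 1.0, 0.2, -1.0, weights=(2.0, 1.0))
        z2, p2 = ps.combine_evidence(0.2, -1.0, 0.01, 1.0, weights=(1.0, 2.0))
        assert z1 == pytest.approx(z2)
        assert p1 == pytest.approx(p2)


def brute_bh(p):
    """Textbook step-up with monotonicity enforcement."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBHFDR:
    def test_worked_example(self):
        np.testing.assert_allclose(ps.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones_and_singleton(self):
        np.testing.assert_allclose(ps.bh_fdr([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_allclose(ps.bh_fdr([0.37]), [0.37])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 40))
            np.testing.assert_allclose(ps.bh_fdr(p), brute_bh(p), atol=1e-12)

    def test_nan_passthrough(self):
        out = ps.bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], brute_bh([0.01, 0.5]))


class TestRankExport:
    def _frame(self, genes, zs):
        return pd.DataFrame(
            {"gene": genes, "z_combined": zs, "status": [STATUS_OK] * len(genes)}
        )

    def test_sorted_descending(self, tmp_path):
        path = tmp_path / "x.rnk"
        ps.export_rank_file(self._frame(["a", "b", "c"], [2.0, -1.0, 0.5]), path)
        out = read_rank_file(path)
        assert list(out["gene"]) == ["a", "c", "b"]
        np.testing.assert_allclose(out["z"], [2.0, 0.5, -1.0])

    def test_clipping_on_write(self, tmp_path):
        path = tmp_path / "x.rnk"
        ps.export_rank_file(self._frame(["a", "b"], [50.0, 0.0]), path, clip=10.0)
        assert read_rank_file(path)["z"].max() == 10.0

    def test_duplicate_symbols_error(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate"):
            ps.export_rank_file(self._frame(["a", "a"], [1.0, 2.0]), tmp_path / "x.rnk")


class TestHurdleModel:
    def test_model_results_roundtrip(self, exocrine_data, tmp_path):
        m = exocrine_data["m"]
        truth = exocrine_data["truth"]
        detected = (m.counts > 0).sum(axis=0)
        genes = [g for g, d in zip(m.genes, detected) if d >= 25][:30]
        model = HurdleModel(
            m,
            truth.activity_true.to_numpy(),
            covariates=("subtype", "donor", "context", "n_genes_detected"),
            genes=genes,
        )
        res = model.fit()
        frame = res.frame
        assert len(frame) == 30
        ok = frame[frame["status"] == STATUS_OK]
        assert len(ok) > 20
        # invariants on the ok rows
        np.testing.assert_allclose(ok["OR_det"], np.exp(ok["logOR_det"]))
        assert ((ok["p_det"] > 0) & (ok["p_det"] <= 1)).all()
        assert (np.sign(ok["z_det"]) == np.sign(ok["logOR_det"])).all()
        assert (ok["FDR_comb"] >= ok["p_combined"] - 1e-12).all()
        # regulon targets should dominate the top of the rank file
        res.export_rank_file(tmp_path / "t.rnk")
        assert (tmp_path / "t.rnk").exists()
        assert "genes fit" in res.summary()
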