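"""Regulon activity scores and covariate residualization."""

import numpy as np
import pandas as pd
import pytest

import pancstate as ps
from pancstate.activity import ActivityMatrix


def _regulon(rows):
    return ps.Regulon(pd.DataFrame(rows, columns=["tf", "target", "mode", "weight"]))


def _matrix(counts):
    n, g = counts.shape
    return ps.log_normalize(
        ps.make_annotated(counts, [f"c{i}" for i in range(n)], [f"g{j}" for j in range(g)])
    )


class TestInferActivity:
    def test_small_regulon_skipped(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.integers(1, 6, size=(10, 8)))
        reg = _regulon(
            [("T1", f"g{j}", 1, 1.0) for j in range(4)]
            + [("T2", f"g{j}", 1, 1.0) for j in range(6)]
        )
        with pytest.warns(UserWarning, match="T1"):
            act = ps.infer_activity(m, reg, min_regulon=5)
        assert list(act.values.columns) == ["T2"]

    def test_no_tf_passes_errors(self):
        m = _matrix(np.ones((4, 6), dtype=int))
        reg = _regulon([("T1", "g0", 1, 1.0)])
        with pytest.raises(ValueError, match="minimum regulon"):
            with pytest.warns(UserWarning):
                ps.infer_activity(m, reg)

    def test_sign_symmetry_cancels(self):
        # equal +1/-1 targets sharing one expression profile: raw score 0
        rng = np.random.default_rng(3)
        base = rng.integers(0, 6, size=(12, 1))
        counts = np.hstack([np.tile(base, (1, 6)), rng.integers(1, 5, size=(12, 4))])
        m = _matrix(counts)
        reg = _regulon(
            [("T", f"g{j}", 1, 1.0) for j in range(3)]
            + [("T", f"g{j}", -1, 1.0) for j in range(3, 6)]
        )
        act = ps.infer_activity(m, reg)
        # raw scores are identically 0, so the z-scaled column is flagged zero
        np.testing.assert_allclose(act.values["T"], 0.0, atol=1e-10)

    def test_z_scaled_per_tf(self, exocrine_data):
        act = ps.infer_activity(exocrine_data["m"], exocrine_data["regulon"])
        vals = act.values.to_numpy()
        np.testing.assert_allclose(vals.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(vals.std(axis=0), 1.0, atol=1e-6)

    def test_recovers_planted_activity(self, exocrine_data):
        act = ps.infer_activity(exocrine_data["m"], exocrine_data["regulon"])
        r = np.corrcoef(act["TF1"], exocrine_data["truth"].activity_true)[0, 1]
        assert r >= 0.8

    def test_invariant_to_target_order(self):
        rng = np.random.default_rng(9)
        m = _matrix(rng.integers(0, 7, size=(15, 10)) + np.eye(15, 10, dtype=int))
        rows = [("T", f"g{j}", (-1) ** j, 1.0 + j / 10) for j in range(6)]
        a1 = ps.infer_activity(m, _regulon(rows))
        a2 = ps.infer_activity(m, _regulon(rows[::-1]))
        np.testing.assert_allclose(a1.values["T"], a2.values["T"], atol=1e-12)

    def test_unaffected_by_non_regulon_genes(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 7, size=(15, 10))
        counts[:, 0] += 1
        m1 = _matrix(counts)
        # permute columns outside the regulon (targets are g0..g4)
        perm = counts.copy()
        perm[:, [5, 6, 7, 8, 9]] = perm[:, [8, 9, 5, 7, 6]]
        m2 = _matrix(perm)
        reg = _regulon([("T", f"g{j}", 1, 1.0) for j in range(5)])
        a1 = ps.infer_activity(m1, reg)
        a2 = ps.infer_activity(m2, reg)
        np.testing.assert_allclose(a1.values["T"], a2.values["T"], atol=1e-12)


class TestResidualize:
    def _meta(self, n, rng):
        return pd.DataFrame(
            {
                "n_genes_detected": rng.integers(100, 500, n).astype(float),
                "pct_mito": rng.uniform(0, 10, n),
                "pct_ribo": rng.uniform(5, 30, n),
                "contamination": rng.uniform(0, 0.4, n),
            },
            index=[f"c{i}" for i in range(n)],
        )

    def test_perfect_fit_gives_zero_residuals(self):
        rng = np.random.default_rng(0)
        meta = self._meta(50, rng)
        vals = pd.DataFrame({"T": 2.0 * meta["n_genes_detected"]})
        act = ActivityMatrix(values=vals)
        out = ps.residualize_activity(act, meta, pc1=rng.normal(size=50))
        np.testing.assert_allclose(out.values["T"], 0.0, atol=1e-8)
        assert "T" in out.degenerate_tfs

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(1)
        meta = self._meta(200, rng)
        vals = pd.DataFrame({"T": rng.normal(size=200)}, index=meta.index)
        pc1 = rng.normal(size=200)
        out = ps.residualize_activity(ActivityMatrix(values=vals), meta, pc1)
        for col in meta.columns:
            r = np.corrcoef(out.values["T"], meta[col])[0, 1]
            assert abs(r) < 1e-8
        assert abs(np.corrcoef(out.values["T"], pc1)[0, 1]) < 1e-8

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        meta = self._meta(30, rng)
        meta["contamination"] = 0.2
        vals = pd.DataFrame({"T": rng.normal(size=30)}, index=meta.index)
        with pytest.warns(UserWarning, match="contamination"):
            out = ps.residualize_activity(ActivityMatrix(values=vals), meta, rng.normal(size=30))
        assert "contamination" not in out.covariates_used

    def test_residual_variance_never_increases(self):
        rng = np.random.default_rng(3)
        meta = self._meta(100, rng)
        Y = rng.normal(size=(100, 3))
        Y[:, 0] += 0.5 * meta["pct_mito"].to_numpy()
        vals = pd.DataFrame(Y, columns=["A", "B", "C"], index=meta.index)
        pc1 = rng.normal(size=100)
        X = np.column_stack(
            [np.ones(100), meta.to_numpy(dtype=float), pc1]
        )
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        assert np.all(resid.var(axis=0) <= Y.var(axis=0) + 1e-12)

    def test_planted_confounder_removed(self, exocrine_data):
        """Mito-contaminated activity: residualization restores the signal."""
        truth = exocrine_data["truth"]
        meta = exocrine_data["m"].cell_meta
        rng = np.random.default_rng(0)
        mito_z = (meta["pct_mito"] - meta["pct_mito"].mean()) / meta["pct_mito"].std()
        contaminated = truth.activity_true.to_numpy() + 0.5 * mito_z.to_numpy()
        vals = pd.DataFrame({"TF1": contaminated}, index=meta.index)
        pc1 = rng.normal(size=len(meta))
        out = ps.residualize_activity(ActivityMatrix(values=vals), meta, pc1)
        r_raw = np.corrcoef(contaminated, truth.activity_true)[0, 1]
        r_resid = np.corrcoef(out.values["TF1"], truth.activity_true)[0, 1]
        assert r_resid > r_raw
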