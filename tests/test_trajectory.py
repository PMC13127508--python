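"""Centroid-MST pseudotime, lineage metrics, and representative selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pancstate as ps
from pancstate.trajectory import LineageSet


def _cluster_cloud(centers, n_per, seed=0, spread=0.1):
    rng = np.random.default_rng(seed)
    pcs, clusters = [], []
    for name, center in centers.items():
        pcs.append(rng.normal(scale=spread, size=(n_per, len(center))) + np.asarray(center))
        clusters += [name] * n_per
    return np.vstack(pcs), np.array(clusters)


class TestInferPseudotime:
    def test_two_cluster_forced_topology(self):
        pcs, clusters = _cluster_cloud({"A": [0, 0], "B": [5, 0]}, 30)
        subtypes = np.where(clusters == "A", "Acinar", "Ductal")
        ls = ps.infer_pseudotime(pcs, clusters, subtypes)
        assert ls.root_cluster == "A"
        assert ls.lineage_paths == [["A", "B"]]
        pt = ls.pseudotime["lineage_1"].to_numpy()
        assert pt[clusters == "A"].mean() < pt[clusters == "B"].mean()
        assert np.nanmin(pt) == 0.0

    def test_collinear_clusters_monotone(self):
        pcs, clusters = _cluster_cloud({"A": [0, 0], "B": [3, 0], "C": [6, 0]}, 40, seed=1)
        subtypes = np.where(clusters == "A", "Acinar", "Ductal")
        ls = ps.infer_pseudotime(pcs, clusters, subtypes)
        assert ls.lineage_paths == [["A", "B", "C"]]
        pt = ls.pseudotime["lineage_1"].to_numpy()
        # pseudotime ordering must track the x coordinate along the line
        rho = stats.spearmanr(pt, pcs[:, 0]).statistic
        assert rho > 0.99

    def test_coincident_centroids_error(self):
        pcs, clusters = _cluster_cloud({"A": [0, 0], "B": [0, 0]}, 10, spread=0.0)
        with pytest.raises(ValueError, match="coincident"):
            ps.infer_pseudotime(pcs, clusters, np.array(["Acinar"] * 20))

    def test_recovers_planted_lineage(self, exocrine_data):
        m, truth, panels = (
            exocrine_data["m"],
            exocrine_data["truth"],
            exocrine_data["panels"],
        )
        scores = ps.score_axes(m, panels, seed=0)
        structure, _ = ps.compute_pc_spaces(m, scores)
        ls = ps.infer_pseudotime(
            structure, m.cell_meta["cluster"].to_numpy(), truth.subtype_true.to_numpy()
        )
        assert ls.root_cluster == "Acinar"
        primary = max(ls.pseudotime.columns, key=lambda c: ls.pseudotime[c].notna().sum())
        col = ls.pseudotime[primary].to_numpy()
        on = ~np.isnan(col)
        rho = stats.spearmanr(col[on], truth.pseudotime_true.to_numpy()[on]).statistic
        assert rho >= 0.7

    def test_rigid_transform_invariance(self):
        pcs, clusters = _cluster_cloud({"A": [0, 0], "B": [4, 1], "C": [8, 0]}, 25, seed=3)
        subtypes = np.where(clusters == "A", "Acinar", "Ductal")
        rng = np.random.default_rng(4)
        q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        ls1 = ps.infer_pseudotime(pcs, clusters, subtypes)
        ls2 = ps.infer_pseudotime(pcs @ q + 13.0, clusters, subtypes)
        pd.testing.assert_frame_equal(ls1.pseudotime, ls2.pseudotime, atol=1e-8)


def _manual_lineage_set(pt_dict, paths=None):
    frame = pd.DataFrame(pt_dict)
    return LineageSet(pseudotime=frame, root_cluster="A", lineage_paths=paths or [])


class TestLineageMetrics:
    def test_ductal_delta_fraction_arithmetic(self):
        # bottom quintile 10% ductal-like, top quintile 90%
        n = 100
        pt = np.arange(n, dtype=float)
        subtypes = np.array(["Acinar"] * n, dtype=object)
        bottom = np.arange(20)
        top = np.arange(80, 100)
        subtypes[bottom[:2]] = "Ductal"        # 10% of bottom window
        subtypes[top[:18]] = "Ductal"          # 90% of top window
        ls = _manual_lineage_set({"lineage_1": pt})
        ls = ps.compute_lineage_metrics(ls, subtypes, q=0.2)
        # windows are inclusive at the quantile boundaries (21 cells here)
        delta = ls.metrics.loc["lineage_1", "ductal_delta"]
        assert delta == pytest.approx(0.8, abs=0.05)
        assert ls.metrics.loc["lineage_1", "pt_range"] == n - 1

    def test_single_subtype_delta_zero(self):
        pt = np.linspace(0, 1, 50)
        ls = _manual_lineage_set({"lineage_1": pt})
        ls = ps.compute_lineage_metrics(ls, np.array(["Ductal"] * 50))
        assert ls.metrics.loc["lineage_1", "ductal_delta"] == 0.0

    def test_identical_lineages_redundancy_one(self):
        pt = np.linspace(0, 2, 40)
        ls = _manual_lineage_set({"lineage_1": pt, "lineage_2": pt.copy()})
        ls = ps.compute_lineage_metrics(ls, np.array(["Acinar"] * 40))
        assert ls.redundancy.loc["lineage_1", "lineage_2"] == pytest.approx(1.0)

    def test_small_overlap_gives_missing_redundancy(self):
        a = np.concatenate([np.linspace(0, 1, 30), np.full(30, np.nan)])
        b = np.concatenate([np.full(25, np.nan), np.linspace(0, 1, 35)])
        ls = _manual_lineage_set({"lineage_1": a, "lineage_2": b})
        ls = ps.compute_lineage_metrics(ls, np.array(["Acinar"] * 60))
        assert np.isnan(ls.redundancy.loc["lineage_1", "lineage_2"])


def _selection_fixture():
    """Four lineages: L1 best, L2 an exact copy of L1, then L3, L4."""
    rng = np.random.default_rng(0)
    base = np.linspace(0, 5, 200) + rng.normal(0, 0.01, 200)
    other = rng.permutation(base)
    third = rng.normal(size=200).cumsum()
    ls = _manual_lineage_set(
        {
            "lineage_1": base,
            "lineage_2": base.copy(),
            "lineage_3": other,
            "lineage_4": third - third.min(),
        }
    )
    subtypes = np.array(["Acinar"] * 100 + ["Ductal"] * 100)
    return ps.compute_lineage_metrics(ls, subtypes)


class TestSelection:
    def test_never_selects_both_copies(self):
        ls = _selection_fixture()
        ls = ps.select_representative_lineages(ls, k=3, lambda_penalty=1.0)
        assert len(ls.selected) == 3
        assert not {"lineage_1", "lineage_2"} <= set(ls.selected)
        # brute-force check: the greedy pick beats any subset containing both copies
        assert len(set(ls.selected)) == 3

    def test_lambda_zero_is_topk(self):
        ls = _selection_fixture()
        ls = ps.select_representative_lineages(ls, k=2, lambda_penalty=0.0)
        base = ls.selection_scores.sort_values(ascending=False)
        assert set(ls.selected) == set(base.index[:2])

    def test_k_equals_all(self):
        ls = _selection_fixture()
        ls = ps.select_representative_lineages(ls, k=4, lambda_penalty=1.0)
        assert set(ls.selected) == set(ls.pseudotime.columns)

    def test_k_above_eligible_warns(self):
        ls = _selection_fixture()
        with pytest.warns(UserWarning, match="eligible"):
            ls = ps.select_representative_lineages(ls, k=10)
        assert len(ls.selected) == 4


class TestProfiles:
    def _ls(self, activity_shape, n=300, seed=0):
        rng = np.random.default_rng(seed)
        pt = np.sort(rng.uniform(0, 1, n))
        ls = _manual_lineage_set({"lineage_1": pt})
        subtypes = np.where(pt < 0.5, "Acinar", "Ductal")
        if activity_shape == "constant":
            act = np.full(n, 1.3)
        else:  # U-shape: high - low - high
            act = 4 * (pt - 0.5) ** 2
        ls.metrics = pd.DataFrame(index=["lineage_1"])
        ls.selected = ["lineage_1"]
        return ls, act, subtypes

    def test_constant_activity_constant_curve(self):
        ls, act, subtypes = self._ls("constant")
        prof = ps.activity_composition_profile(ls, act, subtypes, n_bins=8)
        np.testing.assert_allclose(prof["lineage_1"]["activity_smoothed"], 1.3, atol=1e-12)

    def test_bin_fractions_sum_to_one(self):
        ls, act, subtypes = self._ls("ushape", seed=1)
        prof = ps.activity_composition_profile(ls, act, subtypes, n_bins=10)
        frame = prof["lineage_1"]
        frac_cols = [c for c in frame.columns if c.startswith("frac_")]
        sums = frame.loc[frame["n"] > 0, frac_cols].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_u_shape_minimum_in_middle_third(self):
        ls, act, subtypes = self._ls("ushape", seed=2)
        prof = ps.activity_composition_profile(ls, act, subtypes, n_bins=9, smooth_window=3)
        curve = prof["lineage_1"]["activity_smoothed"].to_numpy()
        argmin = np.nanargmin(curve)
        assert 3 <= argmin <= 5
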