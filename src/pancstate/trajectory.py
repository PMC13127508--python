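"""Pseudotime lineages, lineage metrics, and representative-lineage selection.

Pseudotime uses a centroid-MST construction: cluster centroids in the
combined PC space are joined by a Euclidean minimum spanning tree; the
root cluster is the one with the highest fraction of acinar-type cells;
lineages are root-to-leaf paths.  A cell's pseudotime along a lineage is
the centroid-path distance from the root to its cluster plus the cell's
signed projection onto the cluster's incoming edge direction, shifted so
each lineage starts at zero.

Lineage metrics (cell count, pseudotime range, early-to-late change in
ductal-like composition) feed a redundancy-penalized greedy selection of
representative lineages, and activity/composition profiles summarize each
selected lineage over scaled pseudotime bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROOT_SUBTYPES = ("Acinar", "Acinar_REG+")
DUCTAL_LIKE = ("Ductal", "Ductal-CFTRhi", "Ductal-MUC5B", "Ductal-injury")


@dataclass
class LineageSet:
    pseudotime: pd.DataFrame  # cells x lineages, NaN off-lineage
    root_cluster: object
    lineage_paths: list[list]
    metrics: pd.DataFrame | None = None
    redundancy: pd.DataFrame | None = None
    selection_scores: pd.Series | None = None
    selected: list[str] = field(default_factory=list)


def infer_pseudotime(
    combined_pcs: np.ndarray,
    cluster_labels,
    subtype_labels,
    root_subtypes: tuple[str, ...] = ROOT_SUBTYPES,
) -> LineageSet:
    """Centroid-MST pseudotime with root-to-leaf lineages."""
    import networkx as nx
    from scipy.sparse.csgraph import minimum_spanning_tree
    from scipy.spatial.distance import cdist

    cluster_labels = pd.Series(np.asarray(cluster_labels))
    subtype_labels = np.asarray(subtype_labels)
    clusters = list(pd.unique(cluster_labels))
    if len(clusters) < 2:
        raise ValueError("infer_pseudotime: need at least 2 clusters")

    centroids = np.vstack(
        [combined_pcs[(cluster_labels == c).to_numpy()].mean(axis=0) for c in clusters]
    )
    dist = cdist(centroids, centroids)
    if np.any(dist[np.triu_indices(len(clusters), k=1)] < 1e-12):
        raise ValueError("infer_pseudotime: coincident cluster centroids")

    # root: cluster with the highest acinar-type fraction
    fractions = []
    for c in clusters:
        mask = (cluster_labels == c).to_numpy()
        fractions.append(np.isin(subtype_labels[mask], root_subtypes).mean())
    root_idx = int(np.argmax(fractions))

    mst = minimum_spanning_tree(dist).toarray()
    graph = nx.Graph()
    graph.add_nodes_from(range(len(clusters)))
    for i, j in zip(*np.nonzero(mst)):
        graph.add_edge(int(i), int(j), weight=float(dist[i, j]))

    leaves = [n for n in graph.nodes if graph.degree[n] == 1 and n != root_idx]
    if not leaves:  # root itself is the only leaf (2-node tree handled above)
        leaves = [n for n in graph.nodes if n != root_idx]
    paths = [nx.shortest_path(graph, root_idx, leaf, weight="weight") for leaf in sorted(leaves)]

    # distance from root to each cluster along the tree
    root_dist = dict(nx.single_source_dijkstra_path_length(graph, root_idx, weight="weight"))

    cluster_pos = {c: i for i, c in enumerate(clusters)}
    cell_cluster_idx = cluster_labels.map(cluster_pos).to_numpy()

    # incoming edge direction per cluster on each path (root uses its first
    # outgoing edge); projection of the cell offset onto that direction
    n_cells = combined_pcs.shape[0]
    pt = {}
    for li, path in enumerate(paths):
        name = f"lineage_{li + 1}"
        col = np.full(n_cells, np.nan)
        on_path = set(path)
        for k, node in enumerate(path):
            if k == 0:
                direction = centroids[path[1]] - centroids[path[0]]
            else:
                direction = centroids[node] - centroids[path[k - 1]]
            direction = direction / np.linalg.norm(direction)
            mask = cell_cluster_idx == node
            offsets = combined_pcs[mask] - centroids[node]
            col[mask] = root_dist[node] + offsets @ direction
        off = ~np.isin(cell_cluster_idx, list(on_path))
        col[off] = np.nan
        finite = col[~np.isnan(col)]
        if finite.size:
            col = col - finite.min()
        pt[name] = col

    index = cluster_labels.index
    return LineageSet(
        pseudotime=pd.DataFrame(pt, index=index),
        root_cluster=clusters[root_idx],
        lineage_paths=[[clusters[i] for i in p] for p in paths],
    )


def compute_lineage_metrics(
    ls: LineageSet,
    subtype_labels,
    ductal_like: tuple[str, ...] = DUCTAL_LIKE,
    q: float = 0.2,
    min_overlap: int = 10,
) -> LineageSet:
    """Fill per-lineage metrics and the lineage-lineage redundancy matrix.

    ductal_delta is the ductal-like fraction among cells in the top-q
    pseudotime window minus the same in the bottom-q window.
    """
    subtype_labels = np.asarray(subtype_labels)
    is_ductal = np.isin(subtype_labels, ductal_like)
    rows = []
    for name in ls.pseudotime.columns:
        col = ls.pseudotime[name].to_numpy()
        on = ~np.isnan(col)
        n = int(on.sum())
        if n < 2:
            rows.append({"lineage": name, "n_cells": n, "pt_range": np.nan, "ductal_delta": np.nan})
            continue
        vals = col[on]
        lo, hi = np.quantile(vals, [q, 1.0 - q])
        early = on & (col <= lo)
        late = on & (col >= hi)
        delta = float(is_ductal[late].mean() - is_ductal[early].mean())
        rows.append(
            {
                "lineage": name,
                "n_cells": n,
                "pt_range": float(vals.max() - vals.min()),
                "ductal_delta": delta,
            }
        )
    metrics = pd.DataFrame(rows).set_index("lineage")

    names = list(ls.pseudotime.columns)
    red = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            both = ls.pseudotime[[a, b]].dropna()
            if len(both) < min_overlap:
                red.loc[a, b] = red.loc[b, a] = np.nan
            else:
                x, y = both[a].to_numpy(), both[b].to_numpy()
                if x.std() == 0 or y.std() == 0:
                    red.loc[a, b] = red.loc[b, a] = np.nan
                else:
                    r = float(np.corrcoef(x, y)[0, 1])
                    red.loc[a, b] = red.loc[b, a] = r

    ls.metrics = metrics
    ls.redundancy = red
    return ls


def select_representative_lineages(
    ls: LineageSet, k: int = 3, lambda_penalty: float = 1.0
) -> LineageSet:
    """Greedy redundancy-penalized selection of k representative lineages.

    Base score = mean of z-scaled (n_cells, pt_range, ductal_delta); after
    picking the top base score, each next pick maximizes
    base - lambda * max |redundancy with already selected|.
    """
    if ls.metrics is None or ls.redundancy is None:
        raise ValueError("select_representative_lineages: metrics not computed")
    complete = ls.metrics.dropna()
    if len(complete) == 0:
        raise ValueError("select_representative_lineages: no lineage with complete metrics")
    if k > len(complete):
        import warnings

        warnings.warn(
            f"only {len(complete)} eligible lineages for k={k}; selecting all"
        )
        k = len(complete)

    z = complete[["n_cells", "pt_range", "ductal_delta"]].astype(float)
    sd = z.std(ddof=0)
    z = (z - z.mean()) / sd.replace(0, 1.0)
    base = z.mean(axis=1)

    selected: list[str] = []
    candidates = list(base.index)
    first = base.idxmax()
    selected.append(first)
    candidates.remove(first)
    while len(selected) < k and candidates:
        penalized = {}
        for c in candidates:
            reds = [abs(ls.redundancy.loc[c, s]) for s in selected]
            reds = [r for r in reds if not np.isnan(r)]
            worst = max(reds) if reds else 0.0
            penalized[c] = base[c] - lambda_penalty * worst
        pick = max(candidates, key=lambda c: (penalized[c], -candidates.index(c)))
        selected.append(pick)
        candidates.remove(pick)

    ls.selection_scores = base
    ls.selected = selected
    return ls


def activity_composition_profile(
    ls: LineageSet,
    activity: np.ndarray,
    subtype_labels,
    n_bins: int = 10,
    smooth_window: int = 3,
) -> dict[str, pd.DataFrame]:
    """Binned subtype composition and smoothed activity per selected lineage.

    Pseudotime is min-max scaled to [0, 1] per lineage; bins are equal
    width; activity is running-mean smoothed over ``smooth_window`` bins
    (edge-truncated, empty bins skipped).
    """
    if not ls.selected:
        raise ValueError("activity_composition_profile: no selected lineages")
    activity = np.asarray(activity, dtype=float)
    subtype_labels = np.asarray(subtype_labels)
    subtypes = sorted(pd.unique(subtype_labels).tolist())

    out: dict[str, pd.DataFrame] = {}
    for name in ls.selected:
        col = ls.pseudotime[name].to_numpy()
        on = ~np.isnan(col)
        vals = col[on]
        span = vals.max() - vals.min()
        scaled = (vals - vals.min()) / span if span > 0 else np.zeros_like(vals)
        bins = np.minimum((scaled * n_bins).astype(int), n_bins - 1)

        act_on = activity[on]
        sub_on = subtype_labels[on]
        records = []
        raw_act = np.full(n_bins, np.nan)
        for b in range(n_bins):
            mask = bins == b
            rec = {"bin": b, "n": int(mask.sum())}
            if mask.any():
                raw_act[b] = act_on[mask].mean()
                for s in subtypes:
                    rec[f"frac_{s}"] = float((sub_on[mask] == s).mean())
            else:
                for s in subtypes:
                    rec[f"frac_{s}"] = np.nan
            records.append(rec)

        half = smooth_window // 2
        smoothed = np.full(n_bins, np.nan)
        for b in range(n_bins):
            lo, hi = max(0, b - half), min(n_bins, b + half + 1)
            window = raw_act[lo:hi]
            window = window[~np.isnan(window)]
            if window.size:
                smoothed[b] = window.mean()
        frame = pd.DataFrame(records).set_index("bin")
        frame["activity_mean"] = raw_act
        frame["activity_smoothed"] = smoothed
        out[name] = frame
    return out
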