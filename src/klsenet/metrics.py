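"""Weighted graph metrics on the fully weighted, unthresholded KLS matrix.

Conventions
-----------
* Edge lengths for path-based metrics are the reciprocal weights 1/w
  (strong similarity = short functional distance).
* "Degree" on a complete weighted graph is nodal strength (sum of weights):
  the binary degree would be the constant n - 1.
* Clustering uses the Onnela geometric-mean triangle intensity on
  max-normalized weights; local efficiency uses the weighted neighbour-
  subgraph form with shortest distances computed inside the neighbour
  subgraph.
* Hubs score one point per criterion for membership in the top 20 % of
  nodes by (a) highest degree, (b) lowest nodal path length, (c) lowest
  clustering coefficient, (d) highest betweenness; a node with score >= 2
  is a hub.

All functions accept either a :class:`~klsenet.network.ConnectivityMatrix`
(node sets are parcel ids) or a plain symmetric weight array (node sets are
row indices).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy.sparse.csgraph import shortest_path

from .atlas import ParcellationAtlas
from .exceptions import InputError, UndefinedMetricError
from .network import ConnectivityMatrix

__all__ = [
    "mean_strength",
    "distance_matrix",
    "nodal_path_length",
    "characteristic_path_length",
    "weighted_clustering",
    "local_efficiency",
    "betweenness",
    "compute_nodal_metrics",
    "identify_hubs",
    "count_hubs_by_scope",
    "threshold_edges",
    "network_summaries",
]


def _resolve(matrix, nodes=None) -> np.ndarray:
    """Return the (induced) weight submatrix for a node set."""
    if isinstance(matrix, ConnectivityMatrix):
        w = matrix.weights if nodes is None else matrix.submatrix(nodes)
    else:
        w = np.asarray(matrix, dtype=float)
        if nodes is not None:
            idx = np.asarray(list(nodes), dtype=int)
            w = w[np.ix_(idx, idx)]
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise InputError("weight matrix must be square")
    return w


def _indices(matrix, nodes) -> np.ndarray:
    if isinstance(matrix, ConnectivityMatrix):
        return matrix.indices_of(nodes)
    return np.asarray(list(nodes), dtype=int)


def mean_strength(matrix, set_a=None, set_b=None) -> float:
    """Mean edge weight within a node set, or between two disjoint sets.

    Within-set: mean over unordered pairs, diagonal excluded.  Between-set:
    mean of w_ij over i in A, j in B.
    """
    if set_b is not None:
        if set_a is None:
            raise InputError("set_a required when set_b is given")
        ia = _indices(matrix, set_a)
        ib = _indices(matrix, set_b)
        if ia.size == 0 or ib.size == 0:
            raise InputError("node sets must be non-empty")
        if np.intersect1d(ia, ib).size:
            raise InputError("set_a and set_b must be disjoint")
        w = matrix.weights if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, float)
        return float(w[np.ix_(ia, ib)].mean())
    w = _resolve(matrix, set_a)
    n = w.shape[0]
    if n < 2:
        raise UndefinedMetricError("within-set mean strength needs >= 2 nodes")
    iu = np.triu_indices(n, k=1)
    return float(w[iu].mean())


def _length_matrix(w: np.ndarray) -> np.ndarray:
    off = ~np.eye(w.shape[0], dtype=bool)
    if np.any(w[off] <= 0):
        raise InputError("all off-diagonal weights must be positive")
    lengths = np.zeros_like(w)
    lengths[off] = 1.0 / w[off]
    return lengths


def distance_matrix(matrix, nodes=None) -> np.ndarray:
    """All-pairs shortest-path distances on edge lengths 1/w (Dijkstra)."""
    w = _resolve(matrix, nodes)
    d = shortest_path(_length_matrix(w), method="D", directed=False)
    return np.asarray(d)


def nodal_path_length(matrix, nodes=None) -> np.ndarray:
    """Per-node mean shortest distance to all other nodes."""
    d = distance_matrix(matrix, nodes)
    n = d.shape[0]
    if n < 2:
        raise UndefinedMetricError("nodal path length needs >= 2 nodes")
    return (d.sum(axis=1)) / (n - 1)


def characteristic_path_length(matrix, nodes=None) -> float:
    """Mean shortest distance over all ordered pairs within the set."""
    return float(nodal_path_length(matrix, nodes).mean())


def weighted_clustering(matrix, nodes=None) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering on max-normalized weights.

    C_i = sum_{j!=h} (w'_ij w'_ih w'_jh)^(1/3) / (k_i (k_i - 1)) with
    w' = w / max(w); returns (per-node C_i, average).
    """
    w = _resolve(matrix, nodes)
    n = w.shape[0]
    if n < 3:
        raise UndefinedMetricError("clustering needs >= 3 nodes")
    off = ~np.eye(n, dtype=bool)
    wmax = w[off].max()
    if wmax <= 0:
        raise InputError("weights must be positive")
    what = np.where(off, w / wmax, 0.0)
    cr = np.cbrt(what)
    triangles = np.diagonal(cr @ cr @ cr)
    k = (what > 0).sum(axis=1)
    denom = k * (k - 1)
    c = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    return c, float(c.mean())


def local_efficiency(matrix, nodes=None) -> tuple[np.ndarray, float]:
    """Weighted local efficiency (neighbour-subgraph efficiency).

    E_loc,i = sum_{j,h in N_i, j!=h} (w_ij w_ih / d_jh(N_i))^(1/3)
              / (k_i (k_i - 1)),
    where d_jh(N_i) are shortest distances on lengths 1/w restricted to the
    subgraph induced by i's neighbours.
    """
    w = _resolve(matrix, nodes)
    n = w.shape[0]
    if n < 3:
        raise UndefinedMetricError("local efficiency needs >= 3 nodes")
    e = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero((w[i] > 0) & (np.arange(n) != i))
        k = nb.size
        if k < 2:
            continue
        sub = w[np.ix_(nb, nb)]
        d = shortest_path(_length_matrix(sub), method="D", directed=False)
        off = ~np.eye(k, dtype=bool)
        inv_d = np.zeros_like(d)
        inv_d[off] = 1.0 / d[off]
        v = np.cbrt(w[i, nb])
        e[i] = v @ np.cbrt(inv_d) @ v / (k * (k - 1))
    return e, float(e.mean())


def betweenness(matrix, nodes=None) -> np.ndarray:
    """Weighted betweenness centrality on lengths 1/w (Brandes, endpoints
    excluded, unnormalized counts of unordered source-target pairs)."""
    w = _resolve(matrix, nodes)
    g = nx.from_numpy_array(_length_matrix(w))
    bc = nx.betweenness_centrality(g, weight="weight", normalized=False)
    return np.array([bc[i] for i in range(w.shape[0])])


def compute_nodal_metrics(matrix, nodes=None, include_local_efficiency: bool = True) -> pd.DataFrame:
    """Per-node table: degree (strength), path length, clustering,
    betweenness (the four hub criteria) and optionally local efficiency."""
    w = _resolve(matrix, nodes)
    if isinstance(matrix, ConnectivityMatrix):
        ids = matrix.node_ids if nodes is None else np.asarray(list(nodes), dtype=int)
    else:
        ids = np.arange(w.shape[0]) if nodes is None else np.asarray(list(nodes), dtype=int)
    n = w.shape[0]
    off = ~np.eye(n, dtype=bool)
    out = pd.DataFrame({"node_id": ids})
    out["degree"] = np.where(off, w, 0.0).sum(axis=1)
    out["path_length"] = nodal_path_length(w)
    out["clustering"] = weighted_clustering(w)[0]
    if include_local_efficiency:
        out["local_efficiency"] = local_efficiency(w)[0]
    out["betweenness"] = betweenness(w)
    return out


def _top_k(values: np.ndarray, ids: np.ndarray, k: int, highest: bool) -> np.ndarray:
    """Boolean flags for the k top (or bottom) nodes; ties at the cutoff
    broken by ascending node id for determinism."""
    key = -values if highest else values
    order = np.lexsort((ids, key))
    flags = np.zeros(values.size, dtype=bool)
    flags[order[:k]] = True
    return flags


def identify_hubs(nodal: pd.DataFrame, top_fraction: float = 0.20) -> pd.DataFrame:
    """Hub table from a nodal-metrics table.

    Flags exactly round(top_fraction * n) nodes per criterion; hub score is
    the number of flags and a node is a hub when the score is at least 2.
    """
    n = len(nodal)
    k = int(np.floor(top_fraction * n + 0.5))
    if n < 5 or k < 1:
        raise UndefinedMetricError("hub detection needs >= 5 nodes (one top-20% slot)")
    ids = nodal["node_id"].to_numpy()
    out = nodal.copy()
    out["flag_degree"] = _top_k(nodal["degree"].to_numpy(float), ids, k, highest=True)
    out["flag_path_length"] = _top_k(nodal["path_length"].to_numpy(float), ids, k, highest=False)
    out["flag_clustering"] = _top_k(nodal["clustering"].to_numpy(float), ids, k, highest=False)
    out["flag_betweenness"] = _top_k(nodal["betweenness"].to_numpy(float), ids, k, highest=True)
    flag_cols = ["flag_degree", "flag_path_length", "flag_clustering", "flag_betweenness"]
    out["hub_score"] = out[flag_cols].sum(axis=1)
    out["is_hub"] = out["hub_score"] >= 2
    return out


def count_hubs_by_scope(hubs: pd.DataFrame, atlas: ParcellationAtlas | pd.DataFrame) -> pd.Series:
    """Hub counts per functional network plus the whole-brain total."""
    parcels = atlas.parcels if isinstance(atlas, ParcellationAtlas) else atlas
    network_of = dict(zip(parcels["parcel_id"].astype(int), parcels["network"]))
    nets = list(dict.fromkeys(parcels["network"]))
    counts = {net: 0 for net in nets}
    for _, row in hubs.iterrows():
        if row["is_hub"]:
            counts[network_of[int(row["node_id"])]] += 1
    counts["whole_brain"] = int(hubs["is_hub"].sum())
    return pd.Series(counts, name="n_hubs")


def threshold_edges(matrix, threshold: float = 0.80) -> pd.DataFrame:
    """Edges with weight >= threshold, for connectome visualization export
    only; metrics always use the full weighted matrix."""
    if not (0 < threshold <= 1):
        raise InputError("threshold must be in (0, 1]")
    w = _resolve(matrix)
    ids = matrix.node_ids if isinstance(matrix, ConnectivityMatrix) else np.arange(w.shape[0])
    iu, ju = np.triu_indices(w.shape[0], k=1)
    keep = w[iu, ju] >= threshold
    return pd.DataFrame(
        {"node_i": ids[iu[keep]], "node_j": ids[ju[keep]], "weight": w[iu, ju][keep]}
    )


def network_summaries(
    matrix: ConnectivityMatrix,
    atlas: ParcellationAtlas | pd.DataFrame,
    include_pairs: bool = True,
    metrics: tuple[str, ...] = ("mean_strength", "char_path_length", "clustering", "local_efficiency"),
) -> pd.DataFrame:
    """Scope-level summaries: whole brain, each functional network, and
    (optionally) every between-network pair.  Pair scopes carry mean
    strength only.  Networks with too few retained nodes for a metric get
    NaN for that metric."""
    parcels = atlas.parcels if isinstance(atlas, ParcellationAtlas) else atlas
    retained = set(int(i) for i in matrix.node_ids)
    nets = list(dict.fromkeys(parcels["network"]))
    members = {
        net: [int(p) for p in parcels.loc[parcels["network"] == net, "parcel_id"] if int(p) in retained]
        for net in nets
    }
    rows = []

    def summarize(scope: str, ids) -> dict:
        sub = matrix.submatrix(ids) if ids is not None else matrix.weights
        n = sub.shape[0]
        row: dict = {"scope": scope, "n_nodes": n}
        if "mean_strength" in metrics:
            row["mean_strength"] = mean_strength(sub) if n >= 2 else np.nan
        if "char_path_length" in metrics:
            row["char_path_length"] = characteristic_path_length(sub) if n >= 2 else np.nan
        if "clustering" in metrics:
            row["clustering"] = weighted_clustering(sub)[1] if n >= 3 else np.nan
        if "local_efficiency" in metrics:
            row["local_efficiency"] = local_efficiency(sub)[1] if n >= 3 else np.nan
        return row

    rows.append(summarize("whole_brain", None))
    for net in nets:
        rows.append(summarize(net, members[net]))
    if include_pairs:
        for i, a in enumerate(nets):
            for b_ in nets[i + 1 :]:
                row = {"scope": f"{a}__{b_}", "n_nodes": len(members[a]) + len(members[b_])}
                if members[a] and members[b_] and "mean_strength" in metrics:
                    row["mean_strength"] = mean_strength(matrix, members[a], members[b_])
                else:
                    row["mean_strength"] = np.nan
                rows.append(row)
    return pd.DataFrame(rows)
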