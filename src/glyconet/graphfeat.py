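"""Structural graph features of glycans and the feature-based baseline.

Forty-two deterministic features are computed per glycan graph: eleven
scalar shape/degree/core descriptors and {max, min, mean, variance}
aggregates of seven node-centrality measures plus {max, mean, variance}
of edge current-flow centrality.  Quantities that are undefined on a
given graph (assortativity of a star, centralities of a single node,
k-cores with k >= 2 on trees, which are always empty) take an explicit
0.0 sentinel so downstream learners always see finite vectors.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .glycoparse import GlycanGraph, glycan_to_graph

_NODE_CENTRALITIES = (
    "betweenness", "closeness", "harmonic", "eigenvector",
    "load", "second_order", "flow",
)
_AGGS = ("max", "min", "mean", "var")

FEATURE_NAMES: tuple[str, ...] = (
    "num_nodes", "num_node_types", "diameter", "branching_number",
    "num_leaves", "degree_assortativity", "nodes_with_degree_ge4",
    "max_leaves_per_node", "mean_leaves_per_node",
    "kcore2_size", "corona2_size",
) + tuple(f"{c}_{a}" for c in _NODE_CENTRALITIES for a in _AGGS) \
  + ("flow_edge_max", "flow_edge_mean", "flow_edge_var")

N_FEATURES = len(FEATURE_NAMES)  # 42


def _aggregate(values: list[float]) -> tuple[float, float, float, float]:
    if not values:
        return (0.0, 0.0, 0.0, 0.0)
    arr = np.asarray(values, dtype=np.float64)
    return (float(arr.max()), float(arr.min()), float(arr.mean()),
            float(arr.var()))


def _centrality(g: nx.Graph, name: str) -> list[float]:
    n = g.number_of_nodes()
    if n < 2:
        return []
    try:
        if name == "betweenness":
            d = nx.betweenness_centrality(g)
        elif name == "closeness":
            d = nx.closeness_centrality(g)
        elif name == "harmonic":
            d = nx.harmonic_centrality(g)
        elif name == "eigenvector":
            d = nx.eigenvector_centrality(g, max_iter=1000, tol=1e-8)
        elif name == "load":
            d = nx.load_centrality(g)
        elif name == "second_order":
            d = nx.second_order_centrality(g)
        elif name == "flow":
            d = nx.current_flow_betweenness_centrality(g)
        else:  # pragma: no cover
            raise KeyError(name)
    except (nx.NetworkXError, nx.PowerIterationFailedConvergence, ZeroDivisionError):
        return []
    return list(d.values())


def compute_graph_features(g: GlycanGraph | nx.Graph) -> np.ndarray:
    """The 42-feature vector of one glycan graph (see :data:`FEATURE_NAMES`)."""
    if isinstance(g, GlycanGraph):
        labels = g.node_labels
        G = g.to_networkx()
    else:
        G = g
        labels = [G.nodes[v].get("label", str(v)) for v in G.nodes]
    n = G.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    deg = dict(G.degree())
    leaves = [v for v, d in deg.items() if d == 1]
    leaf_neighbors = {v: sum(1 for u in G.neighbors(v) if deg[u] == 1)
                      for v in G.nodes}

    feats: dict[str, float] = {
        "num_nodes": float(n),
        "num_node_types": float(len(set(labels))),
        "diameter": float(nx.diameter(G)) if n > 1 else 0.0,
        "branching_number": float(sum(1 for d in deg.values() if d >= 3)),
        "num_leaves": float(len(leaves)),
        "nodes_with_degree_ge4": float(sum(1 for d in deg.values() if d >= 4)),
        "max_leaves_per_node": float(max(leaf_neighbors.values())) if n else 0.0,
        "mean_leaves_per_node": float(np.mean(list(leaf_neighbors.values()))),
        "kcore2_size": float(nx.k_core(G, 2).number_of_nodes()) if n > 1 else 0.0,
        "corona2_size": float(nx.k_corona(G, 2).number_of_nodes()) if n > 1 else 0.0,
    }
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assort = nx.degree_assortativity_coefficient(G)
        feats["degree_assortativity"] = 0.0 if not np.isfinite(assort) else float(assort)
    except (ValueError, ZeroDivisionError):
        feats["degree_assortativity"] = 0.0

    for cname in _NODE_CENTRALITIES:
        mx, mn, me, va = _aggregate(_centrality(G, cname))
        feats[f"{cname}_max"] = mx
        feats[f"{cname}_min"] = mn
        feats[f"{cname}_mean"] = me
        feats[f"{cname}_var"] = va

    edge_vals: list[float] = []
    if n > 1 and G.number_of_edges():
        try:
            edge_vals = list(nx.edge_current_flow_betweenness_centrality(G).values())
        except (nx.NetworkXError, ZeroDivisionError):
            edge_vals = []
    mx, _, me, va = _aggregate(edge_vals)
    feats["flow_edge_max"] = mx
    feats["flow_edge_mean"] = me
    feats["flow_edge_var"] = va

    return np.array([feats[name] for name in FEATURE_NAMES], dtype=np.float64)


def feature_table(glycans: list[str]) -> pd.DataFrame:
    """Feature matrix with one row per glycan, columns :data:`FEATURE_NAMES`."""
    rows = []
    for i, s in enumerate(glycans):
        try:
            rows.append(compute_graph_features(glycan_to_graph(s)))
        except Exception as exc:
            raise ValueError(f"glycan at row {i} failed: {exc}") from exc
    if not rows:
        return pd.DataFrame(np.empty((0, N_FEATURES)), columns=list(FEATURE_NAMES))
    return pd.DataFrame(np.vstack(rows), columns=list(FEATURE_NAMES))


def fit_feature_baseline(X, y, seed: int = 0, test_frac: float = 0.2,
                         n_estimators: int = 100):
    """Random-forest baseline on graph features with an 80/20 held-out split.

    Returns (fitted model, held-out accuracy, importance Series summing to 1).
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import train_test_split

    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_frac, random_state=seed, stratify=y)
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    model.fit(Xtr, ytr)
    acc = float(model.score(Xte, yte))
    importances = pd.Series(model.feature_importances_, index=list(FEATURE_NAMES))
    return model, acc, importances
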