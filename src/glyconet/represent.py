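"""Learned glycan representations and their downstream analyses.

The representation of a glycan is the summed per-block readout of the
trained network, taken directly before the fully connected head
(2 x embed_dim).  Downstream: logistic-regression probes, K-means
cluster agreement (adjusted Rand index), and representation-based
phylogenies — per-taxon mean vectors, a cosine distance matrix and
average-linkage hierarchical clustering exported as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .glycoparse import Vocabulary
from .sweetnet import SweetNet, encode_glycans, make_batch


@dataclass
class SpeciesProfile:
    """Mean representation of one taxon and how many glycans back it."""

    label: str
    vector: np.ndarray
    n_glycans: int


def extract_representations(model: SweetNet, glycans, vocab: Vocabulary,
                            batch_size: int = 64) -> np.ndarray:
    """Representation matrix, one row per glycan in input order."""
    model.eval()
    encoded = encode_glycans(glycans, vocab)
    rows = []
    for s in range(0, len(encoded), batch_size):
        batch = make_batch(encoded[s:s + batch_size])
        rows.append(model.representation(batch).data)
    return np.vstack(rows) if rows else np.empty((0, model.config.repr_dim))


def average_by_group(reps: np.ndarray, group_labels, min_n: int = 1
                     ) -> list[SpeciesProfile]:
    """Arithmetic-mean profile per group; groups below `min_n` excluded."""
    labels = np.asarray(group_labels)
    out = []
    for g in sorted(set(labels.tolist())):
        idx = np.nonzero(labels == g)[0]
        if idx.size < min_n:
            continue
        out.append(SpeciesProfile(label=str(g), vector=reps[idx].mean(axis=0),
                                  n_glycans=int(idx.size)))
    return out


def cosine_distance_matrix(profiles) -> np.ndarray:
    """Pairwise cosine distances ``1 - u.v/(|u||v|)``; zero diagonal."""
    if isinstance(profiles, (list, tuple)) and profiles \
            and isinstance(profiles[0], SpeciesProfile):
        X = np.vstack([p.vector for p in profiles])
    else:
        X = np.asarray(profiles, dtype=np.float64)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero vector has no cosine distance")
    U = X / norms[:, None]
    D = 1.0 - U @ U.T
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def _newick_label(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch
    lengths derived from merge heights."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def render(node: int) -> str:
        if node < n:
            return _newick_label(labels[node])
        a, b, h, _ = Z[node - n]
        a, b = int(a), int(b)
        la = render(a) + f":{(h - heights[a]) / 2:.6g}"
        lb = render(b) + f":{(h - heights[b]) / 2:.6g}"
        heights[node] = h
        return f"({la},{lb})"

    for i, row in enumerate(Z):
        heights[n + i] = row[2]
    return render(n + len(Z) - 1) + ";"


def build_dendrogram(D: np.ndarray, labels: list[str],
                     linkage: str = "average") -> tuple[np.ndarray, str]:
    """Agglomerative clustering of a distance matrix.

    Returns the scipy linkage matrix and a Newick string whose leaves are
    `labels`; branch lengths are half the parent/child merge-height gap.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.shape[0] < 2:
        raise ValueError("need at least 2 groups to build a dendrogram")
    if len(labels) != D.shape[0]:
        raise ValueError("labels do not match distance matrix")
    Z = scipy_linkage(squareform(D, checks=False), method=linkage)
    return Z, linkage_to_newick(Z, list(labels))


def dendrogram_top_split(Z: np.ndarray, labels: list[str]
                         ) -> tuple[set[str], set[str]]:
    """Leaf labels on the two sides of the root merge."""
    n = len(labels)

    def leaves(node: int) -> set[str]:
        if node < n:
            return {labels[node]}
        a, b = int(Z[node - n][0]), int(Z[node - n][1])
        return leaves(a) | leaves(b)

    root = n + len(Z) - 1
    a, b = int(Z[-1][0]), int(Z[-1][1])
    assert root == n + len(Z) - 1
    return leaves(a), leaves(b)


def probe_classifier(reps: np.ndarray, labels, seed: int = 0,
                     test_frac: float = 0.2) -> float:
    """Held-out accuracy of a logistic-regression probe on representations."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    y = np.asarray(labels)
    Xtr, Xte, ytr, yte = train_test_split(reps, y, test_size=test_frac,
                                          random_state=seed, stratify=y)
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(Xtr, ytr)
    return float(clf.score(Xte, yte))


def cluster_agreement(reps: np.ndarray, labels, k: int, seed: int = 0) -> float:
    """Adjusted Rand index between K-means clusters and the given labels."""
    from sklearn.cluster import KMeans
    from sklearn.metrics import adjusted_rand_score

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(np.asarray(reps, dtype=np.float64))
    return float(adjusted_rand_score(np.asarray(labels), assign))
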