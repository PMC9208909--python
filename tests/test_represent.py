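"""Representation extraction, probes, clustering and phylogenies."""

import itertools

import dendropy
import numpy as np
import pytest

from glyconet import (ModelConfig, average_by_group, build_dendrogram,
                      cluster_agreement, cosine_distance_matrix,
                      dendrogram_top_split, extract_representations,
                      linkage_to_newick, probe_classifier)
from glyconet.sweetnet import SweetNet


def test_representation_rows_align_and_duplicate(vocab, corpus):
    model = SweetNet(len(vocab), ModelConfig(embed_dim=16), seed=0)
    reps = extract_representations(model, corpus[:6] + [corpus[0]], vocab)
    assert reps.shape == (7, 32)
    np.testing.assert_allclose(reps[0], reps[6], atol=1e-12)
    assert np.all(np.isfinite(reps))


def test_average_by_group_and_min_n():
    reps = np.array([[1.0, 0.0], [0.0, 1.0], [4.0, 4.0]])
    profiles = average_by_group(reps, ["a", "a", "b"], min_n=1)
    assert {p.label for p in profiles} == {"a", "b"}
    pa = next(p for p in profiles if p.label == "a")
    np.testing.assert_allclose(pa.vector, [0.5, 0.5])
    assert pa.n_glycans == 2
    only_a = average_by_group(reps, ["a", "a", "b"], min_n=2)
    assert [p.label for p in only_a] == ["a"]


def test_cosine_distance_identities():
    D = cosine_distance_matrix(np.array([[1.0, 0.0], [2.0, 0.0],
                                         [0.0, 3.0], [-1.0, 0.0]]))
    assert D[0, 1] == pytest.approx(0.0, abs=1e-12)  # scale invariance
    assert D[0, 2] == pytest.approx(1.0)             # orthogonal
    assert D[0, 3] == pytest.approx(2.0)             # antipodal
    np.testing.assert_allclose(np.diag(D), 0.0)
    np.testing.assert_allclose(D, D.T)
    with pytest.raises(ValueError):
        cosine_distance_matrix(np.array([[0.0, 0.0], [1.0, 0.0]]))


def test_dendrogram_merge_order_and_newick_roundtrip():
    D = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
    Z, newick = build_dendrogram(D, ["a", "b", "c c"])
    assert {int(Z[0][0]), int(Z[0][1])} == {0, 1}  # a,b merge first
    tree = dendropy.Tree.get(data=newick, schema="newick")
    assert {l.taxon.label for l in tree.leaf_node_iter()} == {"a", "b", "c c"}
    left, right = dendrogram_top_split(Z, ["a", "b", "c c"])
    assert {frozenset(left), frozenset(right)} == \
        {frozenset({"a", "b"}), frozenset({"c c"})}


def test_dendrogram_two_groups_and_errors():
    Z, newick = build_dendrogram(np.array([[0.0, 0.4], [0.4, 0.0]]), ["x", "y"])
    assert newick.count(",") == 1 and newick.endswith(";")
    with pytest.raises(ValueError):
        build_dendrogram(np.zeros((1, 1)), ["x"])


def test_dendrogram_input_order_invariance():
    rng = np.random.default_rng(3)
    X = np.vstack([rng.normal(0, 0.05, (3, 4)) + [1, 0, 0, 0],
                   rng.normal(0, 0.05, (3, 4)) + [0, 1, 0, 0]])
    labels = [f"s{i}" for i in range(6)]
    D = cosine_distance_matrix(X)
    Z, _ = build_dendrogram(D, labels)
    perm = rng.permutation(6)
    Zp, _ = build_dendrogram(D[np.ix_(perm, perm)], [labels[i] for i in perm])
    a = {frozenset(s) for s in dendrogram_top_split(Z, labels)}
    b = {frozenset(s) for s in
         dendrogram_top_split(Zp, [labels[i] for i in perm])}
    assert a == b


def test_planted_superclusters_recovered():
    """Two well-separated bundles of species means split at the root."""
    rng = np.random.default_rng(11)
    A = rng.normal(0, 0.1, (5, 8)) + np.r_[np.ones(4), np.zeros(4)]
    B = rng.normal(0, 0.1, (5, 8)) + np.r_[np.zeros(4), np.ones(4)]
    labels = [f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)]
    D = cosine_distance_matrix(np.vstack([A, B]))
    Z, _ = build_dendrogram(D, labels)
    left, right = dendrogram_top_split(Z, labels)
    sides = {frozenset(l[0] for l in left), frozenset(l[0] for l in right)}
    assert sides == {frozenset("A"), frozenset("B")}


def test_probe_classifier_separable_and_shuffled(rng):
    X = np.vstack([rng.normal(0, 0.1, (40, 4)) + [3, 0, 0, 0],
                   rng.normal(0, 0.1, (40, 4)) - [3, 0, 0, 0]])
    y = np.r_[np.zeros(40), np.ones(40)]
    assert probe_classifier(X, y, seed=0) == 1.0
    y_shuffled = rng.permutation(y)
    acc = probe_classifier(X, y_shuffled, seed=0)
    assert acc < 0.85  # near majority frequency, far from separable


def brute_force_ari(a, b):
    """ARI via explicit pair counting (chance-corrected agreement)."""
    n = len(a)
    both = same_a = same_b = 0
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        both += sa and sb
        same_a += sa
        same_b += sb
    total = n * (n - 1) / 2
    exp = same_a * same_b / total
    mx = (same_a + same_b) / 2
    if mx == exp:
        # degenerate: both all-singletons or both one cluster -> identical
        return 1.0 if same_a == same_b else 0.0
    return (both - exp) / (mx - exp)


def test_ari_matches_pair_counting_brute_force():
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(3, 7))
        a = rng.integers(0, 3, n)
        b = rng.integers(0, 3, n)
        if len(set(a)) < 2 and len(set(b)) < 2:
            continue
        assert adjusted_rand_score(a, b) == pytest.approx(
            brute_force_ari(a, b), abs=1e-12)


def test_cluster_agreement_extremes(rng):
    X = np.vstack([rng.normal(0, 0.05, (20, 3)) + [5, 0, 0],
                   rng.normal(0, 0.05, (20, 3)) - [5, 0, 0]])
    y = np.r_[np.zeros(20), np.ones(20)]
    assert cluster_agreement(X, y, k=2, seed=0) == pytest.approx(1.0)
    assert cluster_agreement(X, np.ones(40), k=2, seed=0) == pytest.approx(0.0)


def test_newick_labels_quoted():
    Z = np.array([[0.0, 1.0, 0.5, 2.0]])
    s = linkage_to_newick(Z, ["Homo sapiens", "Sus_scrofa"])
    assert "'Homo sapiens'" in s and s.endswith(";")
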