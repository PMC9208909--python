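"""Splitting, schedule, metrics and training behaviour."""

import itertools

import numpy as np
import pytest

from glyconet import (GeneratorConfig, Metrics, ModelConfig, TrainConfig,
                      context_pretrain, cosine_lr, encode_glycans, evaluate,
                      make_batch, planted_classification, stratified_split,
                      train_classifier)
from glyconet.nn import init_sparse
from glyconet.sweetnet import SweetNet


# ------------------------------------------------------------ splitting
def test_stratified_split_ratio_and_min_class():
    labels = np.array([0] * 10 + [1] * 4 + [2] * 20)
    tr, te = stratified_split(labels, seed=0)
    assert len(np.intersect1d(tr, te)) == 0
    assert np.sum(labels[te] == 0) == 2 and np.sum(labels[tr] == 0) == 8
    assert np.sum(labels[te] == 2) == 4
    assert not np.any(labels[np.concatenate([tr, te])] == 1)  # class of 4 dropped


def test_stratified_split_reproducible_and_small_class_test_presence():
    labels = np.array([0] * 5 + [1] * 7)
    tr1, te1 = stratified_split(labels, seed=42)
    tr2, te2 = stratified_split(labels, seed=42)
    np.testing.assert_array_equal(te1, te2)
    np.testing.assert_array_equal(tr1, tr2)
    assert np.sum(labels[te1] == 0) == 1  # max(1, round(0.2*5))


def test_stratified_split_no_surviving_class():
    with pytest.raises(ValueError):
        stratified_split(np.array([0, 0, 1, 1]), min_class_size=5)


# ------------------------------------------------------------ schedule
def test_cosine_schedule_published_anchors():
    assert cosine_lr(0) == pytest.approx(5e-4)
    assert cosine_lr(40) == pytest.approx(2.5e-4)
    assert cosine_lr(80, floor=0.0) == 0.0


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(early_stop_patience=100, max_epochs=100)
    with pytest.raises(ValueError):
        TrainConfig(loss="hinge")


# ------------------------------------------------------------ metrics
def mcc_gorodkin(y, p, k=3):
    """Independent multiclass MCC from the confusion matrix."""
    C = np.zeros((k, k))
    for a, b in zip(y, p):
        C[a, b] += 1
    t = C.sum(axis=1)
    q = C.sum(axis=0)
    n = C.sum()
    cov_yp = C.trace() * n - t @ q
    cov_yy = n ** 2 - t @ t
    cov_pp = n ** 2 - q @ q
    if cov_yy == 0 or cov_pp == 0:
        return 0.0
    return cov_yp / np.sqrt(cov_yy * cov_pp)


def test_mcc_agrees_with_confusion_matrix_brute_force():
    from sklearn.metrics import matthews_corrcoef
    import warnings

    for y in itertools.product(range(3), repeat=4):
        for p in itertools.product(range(3), repeat=4):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = matthews_corrcoef(y, p)
            assert got == pytest.approx(mcc_gorodkin(y, p), abs=1e-12)


def test_evaluate_perfect_constant_and_inverted(vocab, corpus):
    model = SweetNet(len(vocab), ModelConfig(embed_dim=8, n_classes=2), seed=0)
    enc = encode_glycans(corpus[:8], vocab)
    model.eval()
    logits = model(make_batch(enc)).data
    pred = np.argmax(logits, axis=1)
    m = evaluate(model, (enc, pred))
    assert m.accuracy == 1.0 and m.matthews_correlation == pytest.approx(1.0)
    if len(set(pred)) == 2:
        m2 = evaluate(model, (enc, 1 - pred))
        assert m2.accuracy == 0.0
        assert m2.matthews_correlation == pytest.approx(-1.0)


def test_evaluate_order_invariant(vocab, corpus):
    model = SweetNet(len(vocab), ModelConfig(embed_dim=8, n_classes=2), seed=0)
    enc = encode_glycans(corpus[:10], vocab)
    y = np.arange(10) % 2
    perm = np.random.default_rng(0).permutation(10)
    a = evaluate(model, (enc, y))
    b = evaluate(model, ([enc[i] for i in perm], y[perm]))
    assert a.accuracy == b.accuracy
    assert a.matthews_correlation == pytest.approx(b.matthews_correlation)


# ------------------------------------------------------------ training
@pytest.fixture(scope="module")
def planted_task():
    glycans, labels = planted_classification(
        160, rule_motif="Neu5Ac", cfg=GeneratorConfig(seed=21))
    return glycans, labels


def test_planted_rule_learning_and_history(planted_task):
    """A one-node rule (contains Neu5Ac) is learned to high accuracy."""
    from glyconet import build_vocabulary

    glycans, labels = planted_task
    tr, te = stratified_split(labels, seed=3)
    voc = build_vocabulary([glycans[i] for i in tr])
    enc = encode_glycans(glycans, voc)
    cfg = TrainConfig(max_epochs=25, early_stop_patience=8, seed=3)
    model = init_sparse(SweetNet(len(voc), ModelConfig(n_classes=2), seed=3),
                        seed=3)
    model, history = train_classifier(
        model, ([enc[i] for i in tr], labels[tr]), cfg=cfg)
    assert len(history) <= 25
    assert {"epoch", "lr", "train_loss"} <= set(history[0])
    best = min(h["train_loss"] for h in history)
    assert history[-1]["train_loss"] >= best  # best-so-far is tracked
    metrics = evaluate(model, ([enc[i] for i in te], labels[te]), cfg)
    assert metrics.accuracy >= 0.9
    assert isinstance(metrics, Metrics)


def test_early_stopping_respects_patience(planted_task, vocab):
    """With a frozen learning rate floor the loss plateaus and training
    halts within patience epochs of the best epoch."""
    glycans, labels = planted_task
    enc = encode_glycans(glycans[:40], vocab)
    cfg = TrainConfig(max_epochs=30, early_stop_patience=3, base_lr=1e-12,
                      lr_floor=1e-15, seed=0)
    model = SweetNet(len(vocab), ModelConfig(embed_dim=8, n_classes=2,
                                             dropout_rate=0.0, msd_samples=1),
                     seed=0)
    _, history = train_classifier(model, (enc, labels[:40]), cfg=cfg)
    assert len(history) <= 1 + cfg.early_stop_patience + 1


def test_context_pretrain_deterministic_context(vocab):
    """In a corpus where Neu5Ac is always followed by a2-3, the masked
    linkage is predictable and accuracy beats vocabulary chance."""
    rng = np.random.default_rng(9)
    glycans = []
    for _ in range(60):
        n = int(rng.integers(2, 4))
        parts = []
        for i in range(n):
            parts.append("Neu5Ac(a2-3)" if rng.random() < 0.5 else "Gal(b1-4)")
        glycans.append("".join(parts) + "Glc")
    voc_local = __import__("glyconet").build_vocabulary(glycans)
    model = SweetNet(len(voc_local), ModelConfig(embed_dim=16, n_classes=2,
                                                 dropout_rate=0.0,
                                                 msd_samples=1), seed=4)
    cfg = TrainConfig(max_epochs=15, early_stop_patience=5, seed=4)
    _, acc = context_pretrain(model, glycans, voc_local, cfg)
    assert acc > 2.0 / len(voc_local)


def test_context_pretrain_skips_single_node(vocab):
    model = SweetNet(len(vocab), ModelConfig(embed_dim=8), seed=0)
    cfg = TrainConfig(max_epochs=2, early_stop_patience=1, seed=0)
    with pytest.warns(UserWarning, match="single-node"):
        context_pretrain(model, ["Gal", "Gal(b1-4)Glc", "Man(a1-2)Man"],
                         vocab, cfg)
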