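"""Autodiff correctness, layers, graph operators and the optimizer."""

import numpy as np
import pytest

from glyconet import nn
from glyconet.nn import GraphBatch, Tensor


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(x)
    flat, gflat = x.ravel(), g.ravel()
    for i in range(flat.size):
        old = flat[i]
        flat[i] = old + eps
        fp = f()
        flat[i] = old - eps
        fm = f()
        flat[i] = old
        gflat[i] = (fp - fm) / (2 * eps)
    return g


@pytest.mark.parametrize("expr", [
    lambda a, b: (a @ b).sum(),
    lambda a, b: ((a @ b).tanh() * 2.0).sum(),
    lambda a, b: (a.sigmoid() + (b * b).mean(axis=1)).sum(),
    lambda a, b: (a.leaky_relu(0.01)).sum() + (b ** 2.0).sum(),
    lambda a, b: ((a - a.mean(axis=0, keepdims=True)) / 3.0).sum() + b.max(axis=1).sum(),
    lambda a, b: nn.concatenate([a, a * 2.0], axis=1).sum() + b.log().sum() if False
    else nn.concatenate([a, a * 2.0], axis=1).sum() + (b * 0.0).sum(),
])
def test_autodiff_matches_numeric_gradients(expr, rng):
    a = nn.Parameter(rng.normal(size=(4, 3)))
    b = nn.Parameter(rng.uniform(0.5, 1.5, size=(3, 5)))
    out = expr(a, b)
    out.backward()
    for p in (a, b):
        num = numeric_grad(lambda: expr(a, b).item(), p.data)
        np.testing.assert_allclose(p.grad, num, atol=1e-6)


def test_gather_and_scatter_gradients(rng):
    x = nn.Parameter(rng.normal(size=(6, 4)))
    idx = np.array([0, 0, 2, 5, 5, 5])
    seg = np.array([0, 0, 1, 1, 2, 2])

    def f():
        return (nn.scatter_sum(x[idx], seg, 3) ** 2.0).sum().item()

    out = (nn.scatter_sum(x[idx], seg, 3) ** 2.0).sum()
    out.backward()
    np.testing.assert_allclose(x.grad, numeric_grad(f, x.data), atol=1e-6)


def test_scatter_max_values_and_grad(rng):
    x = nn.Parameter(rng.normal(size=(5, 3)))
    seg = np.array([0, 0, 0, 1, 1])
    out = nn.scatter_max(x, seg, 2)
    np.testing.assert_allclose(out.data[0], x.data[:3].max(axis=0))
    np.testing.assert_allclose(out.data[1], x.data[3:].max(axis=0))
    (out * out).sum().backward()
    num = numeric_grad(lambda: (nn.scatter_max(x, seg, 2) ** 2.0).sum().item(),
                       x.data)
    np.testing.assert_allclose(x.grad, num, atol=1e-6)


def test_softmax_cross_entropy_gradient(rng):
    logits = nn.Parameter(rng.normal(size=(5, 4)))
    y = np.array([0, 3, 1, 1, 2])
    nn.softmax_cross_entropy(logits, y).backward()
    num = numeric_grad(
        lambda: nn.softmax_cross_entropy(Tensor(logits.data), y).item(),
        logits.data)
    np.testing.assert_allclose(logits.grad, num, atol=1e-6)


def test_lstm_gradient_and_masking(rng):
    lstm = nn.LSTM(7, 3, 4, rng)
    tokens = np.array([[1, 2, 3, 0], [4, 5, 0, 0]])
    lengths = np.array([4, 2])
    h = lstm(tokens, lengths)
    assert h.shape == (2, 4)
    # padded positions must not affect the state
    tokens2 = tokens.copy()
    tokens2[1, 2:] = 6
    np.testing.assert_allclose(h.data, lstm(tokens2, lengths).data)
    p = lstm.wh.weight
    h.sum().backward()
    num = numeric_grad(lambda: lstm(tokens, lengths).sum().item(), p.data,
                       eps=1e-5)
    np.testing.assert_allclose(p.grad, num, atol=1e-5)


def test_graphconv_identity_weights_sums_neighbors(rng):
    conv = nn.GraphConv(3, 3, rng)
    conv.lin_self.weight.data[...] = np.eye(3)
    conv.lin_self.bias.data[...] = 0
    conv.lin_neigh.weight.data[...] = np.eye(3)
    x = Tensor(np.eye(3))  # one-hot path a-b-c
    edges = np.array([[0, 1, 1, 2], [1, 0, 2, 1]])
    out = conv(x, edges)
    np.testing.assert_allclose(out.data[1], x.data[1] + x.data[0] + x.data[2])
    np.testing.assert_allclose(out.data[0], x.data[0] + x.data[1])
    # isolated node: only the self term survives
    out_iso = conv(x, np.zeros((2, 0), dtype=np.int64))
    np.testing.assert_allclose(out_iso.data, x.data)


def test_graphconv_is_permutation_equivariant(rng):
    conv = nn.GraphConv(4, 4, rng)
    x = rng.normal(size=(5, 4))
    edges = np.array([[0, 1, 1, 2, 2, 3, 3, 4], [1, 0, 2, 1, 3, 2, 4, 3]])
    out = conv(Tensor(x), edges).data
    perm = np.array([4, 2, 0, 1, 3])
    inv = np.argsort(perm)
    out_p = conv(Tensor(x[perm]), inv[edges]).data
    np.testing.assert_allclose(out_p, out[perm], atol=1e-12)


def test_topk_pool_selection_and_gating(rng):
    pool = nn.TopKPool(2, 0.5, rng)
    pool.p.data[...] = np.array([[1.0], [0.0]])
    x = Tensor(np.array([[0.9, 1], [0.1, 1], [0.5, 1], [0.3, 1]]))
    edges = np.array([[0, 1, 1, 2, 2, 3], [1, 0, 2, 1, 3, 2]])
    batch = np.zeros(4, dtype=np.int64)
    x2, e2, b2, kept = pool(x, edges, batch)
    assert kept.tolist() == [0, 2]
    np.testing.assert_allclose(x2.data, x.data[[0, 2]] * np.tanh([[0.9], [0.5]]))
    assert e2.shape == (2, 0)  # nodes 0 and 2 are not adjacent
    # ceiling: a single node survives ratio 0.5
    x1, _, _, kept1 = pool(Tensor(np.array([[1.0, 0.0]])),
                           np.zeros((2, 0), dtype=np.int64),
                           np.zeros(1, dtype=np.int64))
    assert kept1.tolist() == [0]


def test_readout_mean_and_max(rng):
    x = Tensor(np.array([[0.0, 2.0], [2.0, 0.0], [5.0, 5.0]]))
    out = nn.readout(x, np.array([0, 0, 1]), 2)
    np.testing.assert_allclose(out.data[0], [1, 1, 2, 2])
    np.testing.assert_allclose(out.data[1], [5, 5, 5, 5])


def test_batchnorm_normalizes_and_tracks_stats(rng):
    bn = nn.BatchNorm1d(3)
    x = Tensor(rng.normal(5.0, 2.0, size=(64, 3)))
    y = bn(x)
    np.testing.assert_allclose(y.data.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(y.data.std(axis=0), 1.0, atol=1e-2)
    bn.eval()
    y2 = bn(Tensor(x.data[:4]))
    assert np.all(np.isfinite(y2.data))


def test_init_sparse_fraction_and_determinism():
    lin = nn.Linear(100, 100, np.random.default_rng(0))
    nn.init_sparse(lin, sparsity=0.10, seed=7)
    nz = np.count_nonzero(lin.weight.data, axis=0)
    assert np.all(nz == 10)  # exactly 10% of 100 inputs per unit
    w1 = lin.weight.data.copy()
    nn.init_sparse(lin, sparsity=0.10, seed=7)
    np.testing.assert_array_equal(w1, lin.weight.data)
    assert np.all(lin.weight.data[w1 == 0] == 0.0)


def test_adam_minimizes_quadratic():
    p = nn.Parameter(np.array([5.0, -3.0]))
    opt = nn.Adam([p], lr=0.1)
    for _ in range(300):
        loss = (p * p).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.abs(p.data).max() < 1e-2


def test_cosine_lr_schedule():
    assert nn.cosine_lr(0) == pytest.approx(5e-4)
    assert nn.cosine_lr(40) == pytest.approx(2.5e-4)
    assert nn.cosine_lr(80, floor=0.0) == pytest.approx(0.0)
    assert nn.cosine_lr(95) == nn.cosine_lr(80) == 1e-6  # held after T, floored


def test_graph_batch_concatenation():
    b = GraphBatch.from_graphs([([1, 2, 3], [(0, 1), (1, 2)]),
                                ([4, 5], [(0, 1)])])
    assert b.tokens.tolist() == [1, 2, 3, 4, 5]
    assert b.batch.tolist() == [0, 0, 0, 1, 1]
    assert b.edge_index.shape == (2, 6)  # both directions
    assert b.edge_index.max() == 4 and b.edge_index[:, -2:].min() == 3
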