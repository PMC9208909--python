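"""Graph-batch container, graph convolution operators and TopK pooling.

A batch of glycan graphs is the usual disjoint union: node features are
stacked, ``edge_index`` holds both directions of every undirected edge,
and ``batch`` maps each node to its graph id (sorted ascending).
"""

from __future__ import annotations

import numpy as np

from .layers import Linear, Module
from .tensor import Tensor, concatenate, scatter_max, scatter_mean, scatter_sum


class GraphBatch:
    """Disjoint union of small graphs (token ids, directed edge index, graph ids)."""

    def __init__(self, tokens: np.ndarray, edge_index: np.ndarray,
                 batch: np.ndarray, n_graphs: int):
        self.tokens = tokens
        self.edge_index = edge_index
        self.batch = batch
        self.n_graphs = n_graphs

    @classmethod
    def from_graphs(cls, encoded: list[tuple[list[int], list[tuple[int, int]]]]):
        """Build from (token_ids, undirected_edges) pairs; edges get expanded."""
        tokens: list[int] = []
        src: list[int] = []
        dst: list[int] = []
        batch: list[int] = []
        offset = 0
        for gi, (toks, edges) in enumerate(encoded):
            tokens.extend(toks)
            batch.extend([gi] * len(toks))
            for u, v in edges:
                src.extend((offset + u, offset + v))
                dst.extend((offset + v, offset + u))
            offset += len(toks)
        edge_index = np.array([src, dst], dtype=np.int64).reshape(2, -1)
        return cls(np.array(tokens, dtype=np.int64), edge_index,
                   np.array(batch, dtype=np.int64), len(encoded))


class GraphConv(Module):
    """Morris et al. operator: ``x_i W1 + (sum_j in N(i) x_j) W2 + b``."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.lin_self = Linear(in_dim, out_dim, rng)
        self.lin_neigh = Linear(in_dim, out_dim, rng)
        self.lin_neigh.bias.requires_grad = False  # single bias via lin_self

    def __call__(self, x: Tensor, edge_index: np.ndarray) -> Tensor:
        n = x.shape[0]
        if edge_index.shape[1]:
            agg = scatter_sum(x[edge_index[0]], edge_index[1], n)
        else:
            agg = Tensor(np.zeros_like(x.data))
        return self.lin_self(x) + agg @ self.lin_neigh.weight


class SAGEConv(Module):
    """GraphSAGE (mean aggregator): ``x_i W1 + mean_j x_j W2``."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.lin_self = Linear(in_dim, out_dim, rng)
        self.lin_neigh = Linear(in_dim, out_dim, rng)
        self.lin_neigh.bias.requires_grad = False

    def __call__(self, x: Tensor, edge_index: np.ndarray) -> Tensor:
        n = x.shape[0]
        if edge_index.shape[1]:
            agg = scatter_mean(x[edge_index[0]], edge_index[1], n)
        else:
            agg = Tensor(np.zeros_like(x.data))
        return self.lin_self(x) + agg @ self.lin_neigh.weight


class SGConv(Module):
    """Simple graph convolution: symmetric-normalized propagation then linear."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, k: int = 1):
        super().__init__()
        self.lin = Linear(in_dim, out_dim, rng)
        self.k = k

    def __call__(self, x: Tensor, edge_index: np.ndarray) -> Tensor:
        n = x.shape[0]
        deg = np.bincount(edge_index[1], minlength=n).astype(np.float64) + 1.0
        norm = 1.0 / np.sqrt(deg)
        for _ in range(self.k):
            # self-loop-augmented sym-normalized adjacency
            msg = x * Tensor(norm[:, None])
            if edge_index.shape[1]:
                agg = scatter_sum(msg[edge_index[0]], edge_index[1], n)
            else:
                agg = Tensor(np.zeros_like(x.data))
            x = (agg + msg) * Tensor(norm[:, None])
        return self.lin(x)


class TopKPool(Module):
    """Learnable node scoring; keeps the top ``ceil(ratio*n)`` nodes per graph.

    Scores are ``y = x . p / ||p||``; kept features are gated by ``tanh(y)``
    so the score vector receives gradient through the selection.
    """

    def __init__(self, dim: int, ratio: float, rng: np.random.Generator):
        super().__init__()
        if not 0 < ratio <= 1:
            raise ValueError("pool ratio must be in (0, 1]")
        from .layers import Parameter

        self.p = Parameter(rng.normal(0.0, 0.1, size=(dim, 1)))
        self.ratio = ratio

    def __call__(self, x: Tensor, edge_index: np.ndarray, batch: np.ndarray):
        n = x.shape[0]
        if n == 0:
            raise ValueError("cannot pool an empty node set")
        norm = np.linalg.norm(self.p.data)
        y = (x @ self.p) * (1.0 / max(norm, 1e-12))
        scores = y.data.ravel()
        keep: list[int] = []
        n_graphs = int(batch.max()) + 1 if batch.size else 0
        for g in range(n_graphs):
            idx = np.nonzero(batch == g)[0]
            k = int(np.ceil(self.ratio * idx.size))
            order = idx[np.argsort(-scores[idx], kind="stable")]
            keep.extend(sorted(order[:k]))
        keep_arr = np.array(keep, dtype=np.int64)
        gate = y[keep_arr].tanh()
        x_new = x[keep_arr] * gate
        # induced subgraph, remapped to the new node numbering
        pos = -np.ones(n, dtype=np.int64)
        pos[keep_arr] = np.arange(keep_arr.size)
        if edge_index.shape[1]:
            mask = (pos[edge_index[0]] >= 0) & (pos[edge_index[1]] >= 0)
            new_edges = pos[edge_index[:, mask]]
        else:
            new_edges = np.zeros((2, 0), dtype=np.int64)
        return x_new, new_edges, batch[keep_arr], keep_arr


def readout(x: Tensor, batch: np.ndarray, n_graphs: int) -> Tensor:
    """Per-graph [global mean || global max] over node features."""
    return concatenate([scatter_mean(x, batch, n_graphs),
                        scatter_max(x, batch, n_graphs)], axis=1)
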