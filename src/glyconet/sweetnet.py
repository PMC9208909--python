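"""The SweetNet glycan graph convolutional network.

Architecture: a 128-dimensional node embedding, three blocks of
(graph convolution -> leaky ReLU -> TopK pooling -> [global mean || max]
readout); the three per-block readouts are summed into the glycan
representation (2 x embed_dim), which a three-layer fully connected head
— the middle layer a "boom" expansion — maps to class logits or a
regression output.  The final layer uses multi-sample dropout: several
dropout masks of the penultimate activation are pushed through the last
linear layer and their outputs (or losses) averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .glycoparse import GlycanGraph, Vocabulary, glycan_to_graph
from .nn import GraphBatch, Tensor

_OPERATORS = {"GraphConv": nn.GraphConv, "SAGEConv": nn.SAGEConv, "SGConv": nn.SGConv}


@dataclass
class ModelConfig:
    """Hyperparameters of the SweetNet trunk and head."""

    embed_dim: int = 128
    conv_operator: str = "GraphConv"
    n_blocks: int = 3
    pool_ratio: float = 0.5
    boom_expansion: int = 4
    fc_hidden: int = 128
    dropout_rate: float = 0.2
    msd_samples: int = 8
    leaky_slope: float = 0.01
    n_classes: int = 2
    regression: bool = False

    def __post_init__(self):
        if self.embed_dim <= 0:
            raise ValueError("embed_dim must be positive")
        if not 0 < self.pool_ratio <= 1:
            raise ValueError("pool_ratio must be in (0, 1]")
        if self.conv_operator not in _OPERATORS:
            raise ValueError(f"unknown conv_operator {self.conv_operator!r}")

    @property
    def repr_dim(self) -> int:
        return 2 * self.embed_dim

    def to_dict(self) -> dict:
        return asdict(self)


class SweetNet(nn.Module):
    """Glycan classifier/regressor over token-encoded glycan graphs."""

    def __init__(self, vocab_size: int, config: ModelConfig | None = None,
                 seed: int = 0):
        super().__init__()
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        self.rng = rng
        op = _OPERATORS[cfg.conv_operator]
        self.embedding = nn.Embedding(vocab_size, cfg.embed_dim, rng)
        self.convs = [op(cfg.embed_dim, cfg.embed_dim, rng)
                      for _ in range(cfg.n_blocks)]
        self.pools = [nn.TopKPool(cfg.embed_dim, cfg.pool_ratio, rng)
                      for _ in range(cfg.n_blocks)]
        d_rep, h = cfg.repr_dim, cfg.fc_hidden
        self.fc1 = nn.Linear(d_rep, h, rng)
        self.bn1 = nn.BatchNorm1d(h)
        self.boom_up = nn.Linear(h, cfg.boom_expansion * h, rng)
        self.boom_down = nn.Linear(cfg.boom_expansion * h, h, rng)
        self.bn2 = nn.BatchNorm1d(h)
        out_dim = 1 if cfg.regression else cfg.n_classes
        self.fc_out = nn.Linear(h, out_dim, rng)
        self.drop1 = nn.Dropout(cfg.dropout_rate, rng)
        self.drop2 = nn.Dropout(cfg.dropout_rate, rng)
        self.msd_drop = nn.Dropout(cfg.dropout_rate, rng)

    # -- trunk -----------------------------------------------------------
    def representation(self, batch: GraphBatch) -> Tensor:
        """Summed per-block readouts, directly prior to the FC head."""
        if batch.n_graphs == 0:
            raise ValueError("empty batch")
        cfg = self.config
        x = self.embedding(batch.tokens)
        edges, gmem = batch.edge_index, batch.batch
        total: Tensor | None = None
        for conv, pool in zip(self.convs, self.pools):
            x = conv(x, edges).leaky_relu(cfg.leaky_slope)
            x, edges, gmem, _ = pool(x, edges, gmem)
            r = nn.readout(x, gmem, batch.n_graphs)
            total = r if total is None else total + r
        return total

    def node_embeddings(self, batch: GraphBatch) -> Tensor:
        """Per-node features after the conv stack, pooling disabled.

        Used for masked-node (context) pretraining, where every node must
        survive to be predicted.
        """
        cfg = self.config
        x = self.embedding(batch.tokens)
        for conv in self.convs:
            x = conv(x, batch.edge_index).leaky_relu(cfg.leaky_slope)
        return x

    # -- head ------------------------------------------------------------
    def _penultimate(self, rep: Tensor) -> Tensor:
        cfg = self.config
        h = self.drop1(self.bn1(self.fc1(rep)).leaky_relu(cfg.leaky_slope))
        b = self.boom_down(self.boom_up(h).leaky_relu(cfg.leaky_slope))
        return self.drop2(self.bn2(b).leaky_relu(cfg.leaky_slope))

    def forward(self, batch: GraphBatch, return_representation: bool = False):
        rep = self.representation(batch)
        h = self._penultimate(rep)
        if self.training and self.config.msd_samples > 1:
            outs = [self.fc_out(self.msd_drop(h))
                    for _ in range(self.config.msd_samples)]
            logits = outs[0]
            for o in outs[1:]:
                logits = logits + o
            logits = logits * (1.0 / len(outs))
        else:
            logits = self.fc_out(h)
        if self.config.regression:
            logits = logits.reshape(-1)
        if return_representation:
            return logits, rep
        return logits

    __call__ = forward

    def predict_proba(self, batch: GraphBatch) -> np.ndarray:
        was_training = self.training
        self.eval()
        probs = nn.softmax(self.forward(batch).data, axis=1)
        self.train(was_training)
        return probs


class MaskedNodeHead(nn.Module):
    """Linear decoder from node embeddings back onto the token vocabulary."""

    def __init__(self, model: SweetNet, vocab_size: int, seed: int = 0):
        super().__init__()
        self.trunk = model
        self.decoder = nn.Linear(model.config.embed_dim, vocab_size,
                                 np.random.default_rng(seed))

    def logits_at(self, batch: GraphBatch, positions: np.ndarray) -> Tensor:
        x = self.trunk.node_embeddings(batch)
        return self.decoder(x[positions])


def encode_glycans(glycans: list[str | GlycanGraph], vocab: Vocabulary
                   ) -> list[tuple[list[int], list[tuple[int, int]]]]:
    """Token-encode glycans (strings or parsed graphs) for batching."""
    out = []
    for g in glycans:
        gg = g if isinstance(g, GlycanGraph) else glycan_to_graph(g)
        out.append((vocab.encode_graph(gg), gg.edges))
    return out


def make_batch(encoded, indices=None) -> GraphBatch:
    if indices is not None:
        encoded = [encoded[i] for i in indices]
    return GraphBatch.from_graphs(encoded)
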