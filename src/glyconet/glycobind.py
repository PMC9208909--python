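"""Joint protein-glycan binding regression.

A recurrent (LSTM) encoder reads the label-encoded protein sequence —
for hemagglutinins the core slice covering the binding loops (residues
50..300) when a full-length sequence is available — and a pluggable
glycan encoder (mono/di/tri-saccharide count vector through a dense
layer, or the SweetNet trunk) reads the glycan.  Both representations
are concatenated and a dense head regresses the per-array Z-score of
the interaction under squared-error loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .glycoparse import Vocabulary, build_vocabulary, extract_motifs
from .sweetnet import ModelConfig, SweetNet, encode_glycans, make_batch
from .train import TrainConfig

AA_TOKENS = tuple("ACDEFGHIKLMNPQRSTVWYX")
AA_VOCAB = {a: i for i, a in enumerate(AA_TOKENS)}
AA_UNK = len(AA_TOKENS)  # any letter outside the 20 + X alphabet
N_AA_TOKENS = len(AA_TOKENS) + 1

CORE_START = 50   # 1-based, inclusive
CORE_END = 300


@dataclass
class BindingRecord:
    protein_seq: str
    glycan: str
    z: float
    array_id: str = ""
    host: str = ""
    subtype: str = ""


def zscore_by_array(signals, array_ids) -> np.ndarray:
    """Standardize raw signals to Z-scores within each array (sample sd)."""
    x = np.asarray(signals, dtype=np.float64)
    ids = np.asarray(array_ids)
    z = np.empty_like(x)
    for a in np.unique(ids):
        m = ids == a
        if m.sum() < 2:
            raise ValueError(f"array {a!r} has fewer than 2 measurements")
        sd = x[m].std(ddof=1)
        if sd == 0:
            raise ValueError(f"array {a!r} has zero variance")
        z[m] = (x[m] - x[m].mean()) / sd
    return z


def extract_core(protein_seq: str) -> str:
    """Slice residues 50..300 (1-based, inclusive) of a full-length
    sequence; shorter (partial) sequences pass through unchanged."""
    if len(protein_seq) >= CORE_END:
        return protein_seq[CORE_START - 1:CORE_END]
    return protein_seq


def encode_protein(core_seq: str, aa_vocab: dict | None = None) -> np.ndarray:
    """Label-encode one amino acid per residue; unknown letters map to <unk>."""
    if not core_seq:
        raise ValueError("empty protein sequence")
    vocab = AA_VOCAB if aa_vocab is None else aa_vocab
    unk = AA_UNK if aa_vocab is None else len(aa_vocab)
    return np.array([vocab.get(a, unk) for a in core_seq.upper()], dtype=np.int64)


@dataclass
class BindingModelConfig:
    glycan_encoder: str = "counts_fc"  # or "sweetnet"
    lstm_hidden_dim: int = 128
    protein_embed_dim: int = 16
    glycan_dim: int = 32
    head_hidden: int = 32
    dropout_rate: float = 0.3
    input_dropout: float = 0.2  # on the motif-count vector during training
    max_motif_len: int = 3
    sweetnet: ModelConfig = field(default_factory=lambda: ModelConfig(regression=True))
    seed: int = 0

    def __post_init__(self):
        if self.glycan_encoder not in ("counts_fc", "sweetnet"):
            raise ValueError(f"unknown glycan encoder {self.glycan_encoder!r}")


class BindingModel(nn.Module):
    """LSTM protein encoder + glycan encoder + dense regression head."""

    def __init__(self, config: BindingModelConfig, motif_index: list[str],
                 glycan_vocab: Vocabulary):
        super().__init__()
        self.config = config
        self.motif_index = list(motif_index)
        self.glycan_vocab = glycan_vocab
        rng = np.random.default_rng(config.seed)
        self.rng = rng
        self.lstm = nn.LSTM(N_AA_TOKENS, config.protein_embed_dim,
                            config.lstm_hidden_dim, rng)
        if config.glycan_encoder == "counts_fc":
            self.glycan_fc = nn.Linear(len(self.motif_index), config.glycan_dim, rng)
        else:
            self.trunk = SweetNet(len(glycan_vocab), config.sweetnet,
                                  seed=config.seed)
            self.glycan_fc = nn.Linear(self.trunk.config.repr_dim,
                                       config.glycan_dim, rng)
        in_dim = config.lstm_hidden_dim + config.glycan_dim
        self.head1 = nn.Linear(in_dim, config.head_hidden, rng)
        self.in_drop = nn.Dropout(config.input_dropout, rng)
        self.drop = nn.Dropout(config.dropout_rate, rng)
        self.head2 = nn.Linear(config.head_hidden, 1, rng)
        self._count_cache: dict[str, np.ndarray] = {}
        self._graph_cache: dict[str, tuple] = {}

    # -- encoders -------------------------------------------------------
    def protein_representation(self, seqs: list[str]) -> nn.Tensor:
        """LSTM final hidden state per sequence; duplicates share one pass."""
        unique: dict[str, int] = {}
        inverse = np.empty(len(seqs), dtype=np.int64)
        for i, s in enumerate(seqs):
            core = extract_core(s)
            if core not in unique:
                unique[core] = len(unique)
            inverse[i] = unique[core]
        cores = list(unique)
        lengths = np.array([len(c) for c in cores])
        tmax = int(lengths.max())
        tokens = np.zeros((len(cores), tmax), dtype=np.int64)
        for i, c in enumerate(cores):
            tokens[i, :len(c)] = encode_protein(c)
        h = self.lstm(tokens, lengths)
        return h[inverse]

    def _glycan_counts(self, glycans: list[str]) -> np.ndarray:
        rows = []
        for g in glycans:
            if g not in self._count_cache:
                counts = extract_motifs(g, max_len=self.config.max_motif_len)
                self._count_cache[g] = np.array(
                    [counts.get(m, 0) for m in self.motif_index], dtype=np.float64)
            rows.append(self._count_cache[g])
        return np.vstack(rows)

    def glycan_representation(self, glycans: list[str]) -> nn.Tensor:
        if self.config.glycan_encoder == "counts_fc":
            x = self.in_drop(nn.Tensor(self._glycan_counts(glycans)))
            return self.glycan_fc(x).leaky_relu()
        for g in glycans:
            if g not in self._graph_cache:
                self._graph_cache[g] = encode_glycans([g], self.glycan_vocab)[0]
        batch = make_batch([self._graph_cache[g] for g in glycans])
        rep = self.in_drop(self.trunk.representation(batch))
        return self.glycan_fc(rep).leaky_relu()

    def forward(self, seqs: list[str], glycans: list[str]) -> nn.Tensor:
        p = self.protein_representation(seqs)
        g = self.glycan_representation(glycans)
        h = self.drop(self.head1(nn.concatenate([p, g], axis=1)).leaky_relu())
        return self.head2(h).reshape(-1)

    __call__ = forward


def build_motif_index(glycans, max_len: int = 3) -> list[str]:
    """Sorted union of all length<=max_len motifs over a glycan set."""
    motifs: set[str] = set()
    for g in set(glycans):
        motifs.update(extract_motifs(g, max_len=max_len))
    return sorted(motifs)


def _split_records(records: list[BindingRecord], test_frac: float, seed: int,
                   split_by: str) -> tuple[list[int], list[int]]:
    rng = np.random.default_rng(seed)
    n = len(records)
    if split_by == "array":
        arrays = sorted({r.array_id for r in records})
        arrays = [arrays[i] for i in rng.permutation(len(arrays))]
        n_test = max(1, int(round(test_frac * len(arrays))))
        test_arrays = set(arrays[:n_test])
        test = [i for i, r in enumerate(records) if r.array_id in test_arrays]
        train = [i for i in range(n) if records[i].array_id not in test_arrays]
    else:
        perm = rng.permutation(n)
        n_test = max(1, int(round(test_frac * n)))
        test, train = perm[:n_test].tolist(), perm[n_test:].tolist()
    return train, test


def train_binding(records: list[BindingRecord],
                  config: BindingModelConfig | None = None,
                  train_cfg: TrainConfig | None = None,
                  split_by: str = "record", test_frac: float = 0.2,
                  valid_frac: float = 0.15):
    """Fit the joint binding model on Z-scored records.

    The motif index (counts encoder) and glycan vocabulary are built from
    the *training* glycans only.  A `valid_frac` slice of the training
    records monitors early stopping (best-epoch weights are restored).
    Returns
    ``(model, {"train_mse", "test_mse", "null_mse"}, (train_idx, test_idx))``.
    """
    config = config or BindingModelConfig()
    cfg = train_cfg or TrainConfig(loss="mean-squared-error")
    train_idx, test_idx = _split_records(records, test_frac, cfg.seed, split_by)
    test_recs = [records[i] for i in test_idx]
    if valid_frac > 0:
        rng0 = np.random.default_rng(cfg.seed + 1)
        perm = rng0.permutation(len(train_idx))
        n_va = max(1, int(round(valid_frac * len(train_idx))))
        valid_recs = [records[train_idx[i]] for i in perm[:n_va]]
        train_recs = [records[train_idx[i]] for i in perm[n_va:]]
    else:
        valid_recs = []
        train_recs = [records[i] for i in train_idx]

    train_glycans = [r.glycan for r in train_recs]
    motif_index = build_motif_index(train_glycans, config.max_motif_len)
    vocab = build_vocabulary(sorted(set(train_glycans)))
    model = BindingModel(config, motif_index, vocab)

    y_tr = np.array([r.z for r in train_recs])
    y_te = np.array([r.z for r in test_recs])
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.base_lr,
                  weight_decay=cfg.weight_decay)
    best, best_state, best_epoch = np.inf, model.state_dict(), -1
    n = len(train_recs)
    for epoch in range(cfg.max_epochs):
        opt.lr = nn.cosine_lr(epoch, cfg.base_lr, cfg.cosine_T, cfg.lr_floor)
        model.train()
        order = rng.permutation(n)
        total = 0.0
        for s in range(0, n, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            batch_recs = [train_recs[i] for i in idx]
            pred = model([r.protein_seq for r in batch_recs],
                         [r.glycan for r in batch_recs])
            loss = nn.mse_loss(pred, y_tr[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError("loss became non-finite")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item() * idx.size
        epoch_loss = total / n
        if valid_recs:
            model.eval()
            y_va = np.array([r.z for r in valid_recs])
            monitored = float(np.mean((_predict_records(model, valid_recs)
                                       - y_va) ** 2))
        else:
            monitored = epoch_loss
        if monitored < best - 1e-12:
            best, best_state, best_epoch = monitored, model.state_dict(), epoch
        elif epoch - best_epoch >= cfg.early_stop_patience:
            break
    model.load_state_dict(best_state)
    model.eval()

    def mse_on(recs, y):
        if not recs:
            return float("nan")
        preds = _predict_records(model, recs)
        return float(np.mean((preds - y) ** 2))

    metrics = {
        "train_mse": mse_on(train_recs, y_tr),
        "test_mse": mse_on(test_recs, y_te),
        "null_mse": float(np.mean((y_te - y_tr.mean()) ** 2)) if len(y_te) else
                    float("nan"),
    }
    return model, metrics, (train_idx, test_idx)


def _predict_records(model: BindingModel, records: list[BindingRecord],
                     batch_size: int = 128) -> np.ndarray:
    model.eval()
    out = []
    for s in range(0, len(records), batch_size):
        chunk = records[s:s + batch_size]
        out.append(model([r.protein_seq for r in chunk],
                         [r.glycan for r in chunk]).data)
    return np.concatenate(out) if out else np.empty(0)


def predict_binding(model: BindingModel, protein_seq: str,
                    glycans: list[str]) -> np.ndarray:
    """Predicted Z-score of `protein_seq` against each glycan (eval mode)."""
    model.eval()
    out = []
    for s in range(0, len(glycans), 256):
        chunk = glycans[s:s + 256]
        out.append(model([protein_seq] * len(chunk), chunk).data)
    return np.concatenate(out) if out else np.empty(0)


def residual_report(model: BindingModel, records: list[BindingRecord],
                    groupings: tuple[str, ...] = ("host", "subtype")):
    """Observed-minus-predicted residuals plus global and per-group MSE."""
    preds = _predict_records(model, records)
    obs = np.array([r.z for r in records])
    residuals = obs - preds
    rows = [{"grouping": "all", "group": "all", "n": len(records),
             "mse": float(np.mean(residuals ** 2))}]
    for field_name in groupings:
        values = np.array([getattr(r, field_name) for r in records])
        for g in sorted(set(values.tolist())):
            m = values == g
            if not m.any():
                warnings.warn(f"group {g!r} has no records; omitted")
                continue
            rows.append({"grouping": field_name, "group": g, "n": int(m.sum()),
                         "mse": float(np.mean(residuals[m] ** 2))})
    return residuals, pd.DataFrame(rows)


def extract_protein_representations(model: BindingModel, seqs: list[str]
                                    ) -> tuple[list[str], np.ndarray]:
    """LSTM final-state representation per unique input sequence."""
    model.eval()
    unique = sorted(set(seqs))
    reps = model.protein_representation(unique).data
    return unique, reps
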