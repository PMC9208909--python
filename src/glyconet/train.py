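"""Dataset splitting, the optimization schedule, classifier training and
masked-node context pretraining.

Optimization follows the published recipe: Adam (weight decay 0.001),
starting learning rate 5e-4 decayed by a cosine over 80 epochs, batch
size 32, at most 100 epochs with early stopping after 20 epochs without
improvement of the monitored loss (validation loss when a validation
split exists, else training loss).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .glycoparse import Vocabulary
from .sweetnet import MaskedNodeHead, SweetNet, encode_glycans, make_batch


@dataclass
class TrainConfig:
    batch_size: int = 32
    weight_decay: float = 0.001
    base_lr: float = 5e-4
    cosine_T: int = 80
    max_epochs: int = 100
    early_stop_patience: int = 20
    loss: str = "cross-entropy"  # or binary-cross-entropy, mean-squared-error
    lr_floor: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.base_lr, self.cosine_T, self.max_epochs,
               self.early_stop_patience) <= 0:
            raise ValueError("all schedule fields must be positive")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.loss not in ("cross-entropy", "binary-cross-entropy",
                             "mean-squared-error"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class Metrics:
    loss: float
    accuracy: float
    matthews_correlation: float

    def to_dict(self) -> dict:
        return asdict(self)


def stratified_split(labels, test_frac: float = 0.2, min_class_size: int = 5,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-class 80/20 index split; classes below `min_class_size` dropped.

    Each surviving class contributes ``max(1, round(test_frac * n))``
    test items.  Returns (train_idx, test_idx); disjoint, both sorted.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    kept_any = False
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < min_class_size:
            continue
        kept_any = True
        perm = rng.permutation(idx)
        n_test = max(1, int(round(test_frac * idx.size)))
        test_idx.extend(perm[:n_test])
        train_idx.extend(perm[n_test:])
    if not kept_any:
        raise ValueError(f"no class has >= {min_class_size} members")
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


cosine_lr = nn.cosine_lr


def _loss_fn(cfg: TrainConfig, logits, labels):
    if cfg.loss == "cross-entropy":
        return nn.softmax_cross_entropy(logits, labels)
    if cfg.loss == "binary-cross-entropy":
        return nn.bce_with_logits(logits, labels)
    return nn.mse_loss(logits, labels)


def _epoch_loss(model, cfg, encoded, labels, rng=None, optimizer=None):
    """One pass over the data; trains if an optimizer is given."""
    n = len(encoded)
    order = rng.permutation(n) if rng is not None else np.arange(n)
    total, count = 0.0, 0
    for start in range(0, n, cfg.batch_size):
        idx = order[start:start + cfg.batch_size]
        batch = make_batch(encoded, idx)
        logits = model(batch)
        loss = _loss_fn(cfg, logits, labels[idx])
        if not np.isfinite(loss.data):
            raise FloatingPointError("loss became non-finite; aborting training")
        if optimizer is not None:
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        total += loss.item() * idx.size
        count += idx.size
    return total / max(count, 1)


def train_classifier(model: SweetNet, train_data, valid_data=None,
                     cfg: TrainConfig | None = None):
    """Train a SweetNet classifier; returns (model, history).

    `train_data`/`valid_data` are (encoded_glycans, labels) pairs as
    produced by :func:`glyconet.sweetnet.encode_glycans`.  The model is
    restored to its best-monitored-loss checkpoint before returning.
    """
    cfg = cfg or TrainConfig()
    enc_tr, y_tr = train_data
    y_tr = np.asarray(y_tr)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.base_lr,
                  weight_decay=cfg.weight_decay)
    history: list[dict] = []
    best_loss, best_state, best_epoch = np.inf, model.state_dict(), -1
    for epoch in range(cfg.max_epochs):
        opt.lr = nn.cosine_lr(epoch, cfg.base_lr, cfg.cosine_T, cfg.lr_floor)
        model.train()
        train_loss = _epoch_loss(model, cfg, enc_tr, y_tr, rng=rng, optimizer=opt)
        record = {"epoch": epoch, "lr": opt.lr, "train_loss": train_loss}
        model.eval()
        if valid_data is not None:
            enc_va, y_va = valid_data
            record["valid_loss"] = _epoch_loss(model, cfg, enc_va,
                                               np.asarray(y_va))
            monitored = record["valid_loss"]
        else:
            monitored = train_loss
        history.append(record)
        if monitored < best_loss - 1e-12:
            best_loss, best_state, best_epoch = monitored, model.state_dict(), epoch
        elif epoch - best_epoch >= cfg.early_stop_patience:
            break
    model.load_state_dict(best_state)
    model.eval()
    return model, history


def evaluate(model: SweetNet, data, cfg: TrainConfig | None = None) -> Metrics:
    """Loss, accuracy and multiclass Matthews correlation on a test set."""
    from sklearn.metrics import matthews_corrcoef

    cfg = cfg or TrainConfig()
    encoded, labels = data
    labels = np.asarray(labels)
    model.eval()
    batch = make_batch(encoded)
    logits = model(batch)
    loss = _loss_fn(cfg, logits, labels).item()
    pred = np.argmax(logits.data, axis=1)
    acc = float(np.mean(pred == labels))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mcc = float(matthews_corrcoef(labels, pred))
    return Metrics(loss=loss, accuracy=acc, matthews_correlation=mcc)


def context_pretrain(model: SweetNet, glycans: list[str], vocab: Vocabulary,
                     cfg: TrainConfig | None = None, seed: int | None = None):
    """Masked-node (context) pretraining.

    Per glycan one uniformly chosen node is replaced by ``<mask>`` and the
    model, through a linear decoder over its pre-readout node embedding,
    predicts the hidden token.  Single-node glycans are skipped with a
    warning.  Returns (pretrained model, final masked-node accuracy).
    """
    cfg = cfg or TrainConfig()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    encoded = encode_glycans(glycans, vocab)
    usable = [e for e in encoded if len(e[0]) > 1]
    if len(usable) < len(encoded):
        warnings.warn(f"skipping {len(encoded) - len(usable)} single-node "
                      "glycans in context pretraining")
    if not usable:
        raise ValueError("no glycan with more than one node")
    head = MaskedNodeHead(model, len(vocab), seed=seed)
    opt = nn.Adam(head.parameters(), lr=cfg.base_lr,
                  weight_decay=cfg.weight_decay)

    def masked_pass(indices, train: bool):
        masked, targets, positions = [], [], []
        offset = 0
        for i in indices:
            toks, edges = usable[i]
            pos = int(rng.integers(len(toks)))
            toks2 = list(toks)
            targets.append(toks2[pos])
            toks2[pos] = vocab.mask_index
            masked.append((toks2, edges))
            positions.append(offset + pos)
            offset += len(toks2)
        batch = make_batch(masked)
        logits = head.logits_at(batch, np.array(positions))
        t = np.array(targets)
        loss = nn.softmax_cross_entropy(logits, t)
        if train:
            opt.zero_grad()
            loss.backward()
            opt.step()
        correct = np.argmax(logits.data, axis=1) == t
        return loss.item(), correct

    n = len(usable)
    best, best_epoch = np.inf, -1
    for epoch in range(cfg.max_epochs):
        opt.lr = nn.cosine_lr(epoch, cfg.base_lr, cfg.cosine_T, cfg.lr_floor)
        model.train()
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            loss, _ = masked_pass(order[s:s + cfg.batch_size], train=True)
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        if epoch_loss < best - 1e-12:
            best, best_epoch = epoch_loss, epoch
        elif epoch - best_epoch >= cfg.early_stop_patience:
            break
    model.eval()
    correct = []
    for s in range(0, n, cfg.batch_size):
        _, c = masked_pass(np.arange(s, min(s + cfg.batch_size, n)), train=False)
        correct.extend(c)
    return model, float(np.mean(correct))
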