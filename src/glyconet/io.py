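"""Shared I/O: glycan tables, single-file model checkpoints, Newick export."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .glycoparse import Vocabulary, glycan_to_graph
from .glycobind import BindingModel, BindingModelConfig
from .sweetnet import ModelConfig, SweetNet

CHECKPOINT_VERSION = 1


def load_glycan_table(path, strict: bool = False) -> pd.DataFrame:
    """Read a CSV/TSV with a ``glycan`` column; rows are validated by the
    parser.  In skip mode (default) invalid rows are dropped with a
    warning naming their line numbers; in strict mode the first bad row
    aborts."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if "glycan" not in df.columns:
        raise ValueError(f"{path}: missing required 'glycan' column")
    bad: list[tuple[int, str]] = []
    keep = np.ones(len(df), dtype=bool)
    for i, s in enumerate(df["glycan"].astype(str)):
        try:
            glycan_to_graph(s)
        except Exception as exc:
            if strict:
                raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
            bad.append((i + 2, str(exc)))
            keep[i] = False
    if bad:
        warnings.warn(f"{path}: skipped {len(bad)} unparseable rows "
                      f"(lines {[b[0] for b in bad]})")
    return df[keep].reset_index(drop=True)


def save_checkpoint(model, path) -> None:
    """Write a single-file .npz checkpoint embedding config + vocabulary."""
    if isinstance(model, SweetNet):
        meta = {"format_version": CHECKPOINT_VERSION, "kind": "sweetnet",
                "config": model.config.to_dict(), "vocab": None}
    elif isinstance(model, BindingModel):
        cfg = vars(model.config).copy()
        cfg["sweetnet"] = cfg["sweetnet"].to_dict()
        meta = {"format_version": CHECKPOINT_VERSION, "kind": "binding",
                "config": cfg, "motif_index": model.motif_index,
                "vocab": model.glycan_vocab.token_to_index}
    else:
        raise TypeError(f"cannot checkpoint {type(model).__name__}")
    if isinstance(model, SweetNet):
        meta["vocab_size"] = model.embedding.weight.data.shape[0]
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def attach_vocab(model: SweetNet, vocab: Vocabulary) -> SweetNet:
    model.vocab = vocab
    return model


def load_checkpoint(path):
    """Restore a model from :func:`save_checkpoint`; eval-mode predictions
    are bit-identical to the saved model's."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("format_version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"checkpoint format {meta.get('format_version')!r} not "
                f"supported (expected {CHECKPOINT_VERSION})")
        state = {k[len("param/"):]: z[k] for k in z.files
                 if k.startswith("param/")}
    if meta["kind"] == "sweetnet":
        model = SweetNet(meta["vocab_size"], ModelConfig(**meta["config"]))
    elif meta["kind"] == "binding":
        cfg_d = dict(meta["config"])
        cfg_d["sweetnet"] = ModelConfig(**cfg_d["sweetnet"])
        model = BindingModel(BindingModelConfig(**cfg_d),
                             meta["motif_index"],
                             Vocabulary(meta["vocab"]))
    else:
        raise ValueError(f"unknown checkpoint kind {meta['kind']!r}")
    model.load_state_dict(state)
    model.eval()
    return model


def write_newick(newick: str, path) -> None:
    """Write a Newick string (terminated with ';') to a file."""
    text = newick if newick.rstrip().endswith(";") else newick + ";"
    Path(path).write_text(text + "\n")


def graphs_to_jsonl(glycans: list[str], path) -> None:
    """One JSON object per glycan: nodes, kinds, edges (the parse output)."""
    with open(path, "w") as fh:
        for s in glycans:
            g = glycan_to_graph(s)
            fh.write(json.dumps({"source": s, "nodes": g.node_labels,
                                 "kinds": g.node_kinds,
                                 "edges": [list(e) for e in g.edges]}) + "\n")
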