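"""Self-supervised context pretraining: predict a masked node's identity.

In this corpus Neu5Ac is always attached through a2-3 while Gal uses
b1-4, so a masked linkage is predictable from its neighbours.  The
masked-node accuracy after pretraining should far exceed vocabulary
chance (1/|vocab|).
"""

import numpy as np

import glyconet as gn
from glyconet.sweetnet import ModelConfig, SweetNet

rng = np.random.default_rng(7)
glycans = []
for _ in range(80):
    parts = ["Neu5Ac(a2-3)" if rng.random() < 0.5 else "Gal(b1-4)"
             for _ in range(int(rng.integers(2, 5)))]
    glycans.append("".join(parts) + "Glc")

vocab = gn.build_vocabulary(glycans)
model = SweetNet(len(vocab), ModelConfig(embed_dim=32, n_classes=2,
                                         dropout_rate=0.0, msd_samples=1),
                 seed=7)
model, acc = gn.context_pretrain(
    model, glycans, vocab,
    gn.TrainConfig(max_epochs=20, early_stop_patience=6, seed=7))

print(f"masked-node accuracy: {acc:.3f} "
      f"(chance = 1/{len(vocab)} = {1 / len(vocab):.3f})")
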