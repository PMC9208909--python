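"""Build a representation-based phylogeny of synthetic 'species'.

Two clades of species are simulated: one whose glycans are rich in
sialylated motifs (animal-like), one rich in plant-type motifs.  A
SweetNet classifier trained to tell them apart yields glycan
representations; per-species means, cosine distances and average-linkage
clustering produce a dendrogram whose top split recovers the clades.
"""

import numpy as np

import glyconet as gn
from glyconet.nn import init_sparse
from glyconet.sweetnet import ModelConfig, SweetNet, encode_glycans

rng = np.random.default_rng(0)
cfg_a = gn.GeneratorConfig(monosaccharides=("Neu5Ac", "Gal", "GlcNAc", "Man"),
                           seed=1)
cfg_b = gn.GeneratorConfig(monosaccharides=("Xyl", "Rha", "GlcA", "Glc"),
                           seed=2)

glycans, labels, species = [], [], []
for clade, cfg in (("animal", cfg_a), ("plant", cfg_b)):
    g_rng = cfg.rng()
    for sp in range(4):
        for _ in range(12):
            glycans.append(gn.random_glycan(cfg, g_rng))
            labels.append(0 if clade == "animal" else 1)
            species.append(f"{clade}_{sp}")
labels = np.array(labels)

vocab = gn.build_vocabulary(glycans)
encoded = encode_glycans(glycans, vocab)
model = init_sparse(SweetNet(len(vocab), ModelConfig(embed_dim=32,
                                                     n_classes=2), seed=0),
                    seed=0)
model, _ = gn.train_classifier(
    model, (encoded, labels),
    cfg=gn.TrainConfig(max_epochs=15, early_stop_patience=5, seed=0))

reps = gn.extract_representations(model, glycans, vocab)
profiles = gn.average_by_group(reps, species, min_n=5)
D = gn.cosine_distance_matrix(profiles)
Z, newick = gn.build_dendrogram(D, [p.label for p in profiles])
left, right = gn.dendrogram_top_split(Z, [p.label for p in profiles])

print("newick:", newick)
print("root split:", sorted(left), "|", sorted(right))
# The two sides of the root should be the animal_* and plant_* species.
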