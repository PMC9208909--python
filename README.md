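# glyconet

Graph convolutional machine learning on glycans: parse IUPAC-condensed
glycan strings into monosaccharide/linkage graphs, train a SweetNet-style
graph convolutional network on them, analyze the learned representations
(probes, clustering, representation-based phylogenies), regress
protein–glycan binding from glycan-array Z-scores, and identify the
glycan motifs that drive predicted binding.

## Who this is for

Glycobiologists and method developers who want a self-contained, tested
CPU implementation of glycan graph learning: no GPU, no external model
zoo.  Glycans are branched — the only nonlinear biological sequence
class — so sequence models discard exactly the structure that matters;
here both monosaccharides and linkages become nodes of a tree, which
also keeps minimal structures like the Tn antigen (`GalNAc(a1-`, one
sugar plus a dangling linkage) in scope.

## The model

A glycan graph with node tokens `t_i` is classified by

* a 128-dim token embedding,
* three blocks of GraphConv
  `x_i ← x_i W₁ + Σ_{j∈N(i)} x_j W₂ + b` (SAGEConv/SGConv are drop-in
  options), leaky ReLU, TopK pooling (keep ⌈n/2⌉ nodes by learned score
  `x·p/‖p‖`, gate by tanh), and a [global-mean ‖ global-max] readout,
* the three readouts summed into a 256-dim representation,
* an FC head 256→128→(boom 128→512→128)→classes with batch norm,
  leaky ReLUs and multi-sample dropout (8 masks averaged) on the final
  layer.

Training follows the published recipe: Adam, weight decay 1e-3, lr
5e-4 with cosine decay over 80 epochs, batch 32, ≤ 100 epochs, early
stop after 20 stale epochs, sparse (10% nonzero) initialization.  The
binding model couples an LSTM protein encoder (hemagglutinin core,
residues 50–300) with a motif-count or SweetNet glycan encoder to
regress per-array Z-scores; motif enrichment then calls predicted
binders at Z > 1.645 and tests each mono/di/tri-saccharide motif with
one-tailed Welch's t + Holm-Šidák per host, summarized by median rank.

The neural-network layer (reverse-mode autodiff, graph ops, LSTM, Adam)
is implemented in this package on top of numpy — gradient-checked,
deterministic in eval mode, CPU-only.

## Worked example

```bash
python examples/binding_and_enrichment.py
```

prints (seeded, so exactly reproducible; a few minutes on one CPU):

```
1920 binding records, 120 glycans, planted: {'human': 'Neu5Ac(a2-6)Gal', 'duck': 'Neu5Ac(a2-3)Gal'}
test MSE 1.25 (null predictor 2.37)

top enriched motifs (median rank across hosts):
          motif  n_hosts_significant  median_rank
Neu5Ac(a2-3)Gal                    1          1.0
Neu5Ac(a2-6)Gal                    1          1.0
            Gal                    2          2.0
         Neu5Ac                    2          3.0

per-host MSE:
grouping group   n      mse
    host  duck 960 1.003393
    host human 960 1.092685
```

Reading: the joint model nearly halves the null predictor's error
(the variance of Z) on held-out records — close to the unit noise
floor per host — and each planted binding motif is recovered at rank 1
in its own host, with the shared `Neu5Ac` monosaccharide and `Gal`
significant in both hosts, exactly as a sialic-acid-binding rule
should look.  Other examples cover parsing and
the 42 structural graph features, classifier training, masked-node
context pretraining, and representation phylogenies.

A thin CLI wraps the same library calls:

```bash
glyconet simulate classify --n 200 --seed 1 --out glycans.csv
glyconet train --data glycans.csv --out model.npz --seed 1
glyconet features --in glycans.csv --out features.tsv
```

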