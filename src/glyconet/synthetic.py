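"""Synthetic glycans, labeled classification sets and glycan-array-like
binding data with planted, recoverable structure.

The generator emulates the shape of curated glycan corpora: branched
IUPAC-condensed strings over a vocabulary of common monosaccharides and
linkages, label rules driven by planted motifs, and per-array Gaussian
binding signals with motif-dependent shifts (already on the Z-score
scale, as glycan-array data are after per-array standardization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glycoparse import extract_motifs, tokenize_iupac

DEFAULT_MONOSACCHARIDES = (
    "Glc", "Gal", "Man", "GlcNAc", "GalNAc", "Fuc",
    "Neu5Ac", "Neu5Gc", "Xyl", "Kdn", "GlcA", "Rha",
)
DEFAULT_LINKAGES = ("a1-2", "a1-3", "a1-6", "a2-3", "a2-6", "b1-2", "b1-3", "b1-4")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class GeneratorConfig:
    """Shape of the synthetic glycan distribution.

    ``branch_prob`` is the per-attachment probability that a new
    monosaccharide starts a side branch (attaches to a monosaccharide
    that already has a child) rather than extending a chain; at most two
    children per monosaccharide.
    """

    monosaccharides: tuple[str, ...] = DEFAULT_MONOSACCHARIDES
    linkages: tuple[str, ...] = DEFAULT_LINKAGES
    min_monos: int = 3
    max_monos: int = 8
    branch_prob: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not self.monosaccharides or not self.linkages:
            raise ValueError("alphabets must be non-empty")
        if not 0 <= self.branch_prob < 1:
            raise ValueError("branch_prob must be in [0, 1)")
        if not 1 <= self.min_monos <= self.max_monos:
            raise ValueError("need 1 <= min_monos <= max_monos")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def random_tree(m: int, branch_prob: float, rng: np.random.Generator) -> list[int]:
    """Random rooted tree over `m` monosaccharides; node 0 is the reducing end.

    Returns ``parents`` with ``parents[i]`` the parent of node i
    (``parents[0] = -1``); nodes are added in index order.  Each
    attachment branches (picks a parent that already has exactly one
    child) with probability `branch_prob` when such a parent with spare
    capacity exists, else extends a chain from a childless node.
    Children per node are capped at 2.
    """
    parents = [-1]
    n_children = [0]
    for i in range(1, m):
        branch_eligible = [j for j in range(i) if n_children[j] == 1]
        childless = [j for j in range(i) if n_children[j] == 0]
        if branch_eligible and rng.random() < branch_prob:
            parent = int(rng.choice(branch_eligible))
        else:
            parent = int(rng.choice(childless))
        parents.append(parent)
        n_children[parent] += 1
        n_children.append(0)
    return parents


def render_tree(parents: list[int], mono_labels: list[str],
                link_labels: list[str]) -> str:
    """Serialize a labeled tree to IUPAC-condensed (reducing end rightmost).

    ``link_labels[i]`` labels the linkage from node i to its parent
    (unused entry for the root); the first child prints unbracketed,
    further children in square brackets.
    """
    children: dict[int, list[int]] = {}
    for i, p in enumerate(parents):
        if p >= 0:
            children.setdefault(p, []).append(i)

    def emit(node: int) -> str:
        parts = []
        kids = children.get(node, [])
        for rank, c in enumerate(kids):
            sub = emit(c) + f"({link_labels[c]})"
            parts.append(sub if rank == 0 else f"[{sub}]")
        return "".join(parts) + mono_labels[node]

    return emit(0)


def random_glycan(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> str:
    """One random IUPAC-condensed glycan string drawn per `cfg`."""
    rng = cfg.rng() if rng is None else rng
    m = int(rng.integers(cfg.min_monos, cfg.max_monos + 1))
    parents = random_tree(m, cfg.branch_prob, rng)
    monos = [str(rng.choice(cfg.monosaccharides)) for _ in range(m)]
    links = [str(rng.choice(cfg.linkages)) for _ in range(m)]
    return render_tree(parents, monos, links)


def _parse_motif(motif: str) -> tuple[list[str], list[str]]:
    """Split a linear motif string into its monosaccharides and linkages."""
    toks = tokenize_iupac(motif)
    monos = [t for t, k in toks if k == "monosaccharide"]
    links = [t for t, k in toks if k == "linkage"]
    if len(links) != len(monos) - 1:
        raise ValueError(f"motif {motif!r} is not a closed linear chain")
    return monos, links


def _contains(glycan: str, motif: str) -> bool:
    return motif in extract_motifs(glycan, max_len=3)


def glycan_with_motif(motif: str, cfg: GeneratorConfig,
                      rng: np.random.Generator) -> str:
    """Random glycan guaranteed to contain `motif` as a linear chain.

    A random tree is drawn and the motif's labels are written onto a
    random root-ward path of the right length (regenerating the tree
    shape in the rare case no such path exists).
    """
    monos_m, links_m = _parse_motif(motif)
    k = len(monos_m)
    while True:
        m = int(rng.integers(max(cfg.min_monos, k), cfg.max_monos + 1))
        parents = random_tree(m, cfg.branch_prob, rng)
        # root-ward chains of k monosaccharides: start anywhere deep enough
        chains = []
        for start in range(m):
            chain = [start]
            while len(chain) < k and parents[chain[-1]] >= 0:
                chain.append(parents[chain[-1]])
            if len(chain) == k:
                chains.append(chain)
        if not chains:
            continue
        chain = chains[int(rng.integers(len(chains)))]
        monos = [str(rng.choice(cfg.monosaccharides)) for _ in range(m)]
        links = [str(rng.choice(cfg.linkages)) for _ in range(m)]
        # motif reads non-reducing -> reducing; chain runs child -> ancestor
        for pos, node in enumerate(chain):
            monos[node] = monos_m[pos]
            if pos < k - 1:
                links[chain[pos]] = links_m[pos]
        s = render_tree(parents, monos, links)
        if _contains(s, motif):
            return s


def glycan_without_motifs(motifs: list[str], cfg: GeneratorConfig,
                          rng: np.random.Generator, max_tries: int = 200) -> str:
    """Random glycan containing none of `motifs` (rejection sampling)."""
    for _ in range(max_tries):
        s = random_glycan(cfg, rng)
        counts = extract_motifs(s, max_len=3)
        if not any(m in counts for m in motifs):
            return s
    raise RuntimeError("could not sample a motif-free glycan; motifs too generic")


def planted_classification(n: int, rule_motif: str = "Neu5Ac(a2-3)Gal",
                           class_balance: float = 0.5,
                           cfg: GeneratorConfig | None = None
                           ) -> tuple[list[str], np.ndarray]:
    """Labeled glycan set: label 1 iff the glycan contains `rule_motif`.

    Positives get the motif written onto a random chain; negatives are
    rejection-sampled to be motif-free.  Returns (glycans, labels).
    """
    cfg = cfg or GeneratorConfig()
    rng = cfg.rng()
    n_pos = int(round(n * class_balance))
    glycans: list[str] = []
    labels = np.zeros(n, dtype=np.int64)
    for i in range(n):
        if i < n_pos:
            glycans.append(glycan_with_motif(rule_motif, cfg, rng))
            labels[i] = 1
        else:
            glycans.append(glycan_without_motifs([rule_motif], cfg, rng))
    order = rng.permutation(n)
    return [glycans[i] for i in order], labels[order]


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice(list(AA_ALPHABET)))
    return "".join(out)


@dataclass
class PlantedBinding:
    """A synthetic glycan-array panel with a motif-driven binding rule."""

    records: list  # list[BindingRecord]
    glycans: list[str]
    family_motifs: dict[str, str] = field(default_factory=dict)
    effect: float = 2.5
    noise_sd: float = 1.0


def planted_binding(n_proteins: int = 16, n_glycans: int = 120,
                    effect: float = 2.5, noise_sd: float = 1.0,
                    cfg: GeneratorConfig | None = None,
                    protein_length: int = 60,
                    motif_frac: float = 0.3,
                    family_motifs: dict[str, str] | None = None
                    ) -> PlantedBinding:
    """Binding records for proteins of two families probed against one
    glycan panel, one array per protein.

    Each family binds its own planted motif:
    ``z = effect * [glycan contains the family's motif] + N(0, noise_sd^2)``.
    A fraction `motif_frac` of glycans carries each motif (exclusively);
    the rest carry neither, so the per-family null-predictor MSE is
    ``effect^2 * p(1-p) + noise_sd^2`` with ``p = motif_frac``.
    """
    from .glycobind import BindingRecord

    cfg = cfg or GeneratorConfig()
    rng = cfg.rng()
    fams = family_motifs or {"human": "Neu5Ac(a2-6)Gal", "duck": "Neu5Ac(a2-3)Gal"}
    hosts = list(fams)
    motifs = list(fams.values())

    # designed panel composition: exactly round(motif_frac * n) glycans per
    # family motif (exclusive), the rest motif-free, in shuffled order
    n_each = int(round(motif_frac * n_glycans))
    kinds = [0] * n_each + [1] * n_each + [2] * (n_glycans - 2 * n_each)
    glycans: list[str] = []
    for kind in kinds:
        while True:
            if kind < 2:
                g = glycan_with_motif(motifs[kind], cfg, rng)
                if not _contains(g, motifs[1 - kind]):
                    break
            else:
                g = glycan_without_motifs(motifs, cfg, rng)
                break
        glycans.append(g)
    glycans = [glycans[i] for i in rng.permutation(n_glycans)]

    ancestors = {h: random_protein(protein_length, rng) for h in hosts}
    records: list[BindingRecord] = []
    for pi in range(n_proteins):
        host = hosts[pi % len(hosts)]
        seq = mutate_protein(ancestors[host], 0.05, rng)
        motif = fams[host]
        for g in glycans:
            z = effect * float(_contains(g, motif)) + rng.normal(0.0, noise_sd)
            records.append(BindingRecord(
                protein_seq=seq, glycan=g, z=z,
                array_id=f"array{pi}", host=host,
                subtype=f"H{1 + pi % 3}",
            ))
    return PlantedBinding(records=records, glycans=glycans,
                          family_motifs=fams, effect=effect, noise_sd=noise_sd)
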