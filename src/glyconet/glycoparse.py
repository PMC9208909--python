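"""Parsing of IUPAC-condensed glycan strings into node/edge graphs.

Glycans are branched trees of monosaccharides joined by glycosidic
linkages.  In IUPAC-condensed notation linkages sit in parentheses
(``Gal(b1-4)Glc``), branches in square brackets
(``Gal(b1-4)[Fuc(a1-3)]GlcNAc``) and the reducing end is rightmost.
Here *both* monosaccharides and linkages become nodes of an undirected
tree, which keeps single-monosaccharide structures with a dangling
linkage (the Tn antigen, ``GalNAc(a1-``) representable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

MONOSACCHARIDE = "monosaccharide"
LINKAGE = "linkage"

MASK_TOKEN = "<mask>"
UNK_TOKEN = "<unk>"

_NORMALIZE = str.maketrans({
    "α": "a",   # α
    "β": "b",   # β
    "–": "-",   # en dash
    "—": "-",   # em dash
    "−": "-",   # minus sign
})


class GlycanParseError(ValueError):
    """Raised for malformed IUPAC-condensed strings; carries the position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


def normalize_iupac(s: str) -> str:
    """Normalize Unicode variants: Greek anomers to a/b, dashes to '-', strip spaces."""
    return s.translate(_NORMALIZE).replace(" ", "").strip()


def _lex(s: str) -> list[tuple[str, str, int]]:
    """Lex a normalized string into (token, kind, position) triples.

    kinds: monosaccharide, linkage, '[' and ']' pass through as structural
    markers.  A trailing unclosed '(' yields a dangling linkage token.
    """
    out: list[tuple[str, str, int]] = []
    i, n = 0, len(s)
    buf_start = 0
    buf = []

    def flush(pos: int) -> None:
        if buf:
            out.append(("".join(buf), MONOSACCHARIDE, buf_start))
            buf.clear()

    while i < n:
        c = s[i]
        if c == "(":
            flush(i)
            j = s.find(")", i + 1)
            if j == -1:
                # dangling linkage: only legal if it runs to end of string
                tok = s[i + 1:]
                if not tok:
                    raise GlycanParseError("empty linkage token", i)
                out.append((tok, LINKAGE, i + 1))
                return out
            tok = s[i + 1:j]
            if not tok:
                raise GlycanParseError("empty linkage token", i)
            out.append((tok, LINKAGE, i + 1))
            i = j + 1
        elif c == ")":
            raise GlycanParseError("unmatched ')'", i)
        elif c in "[]":
            flush(i)
            out.append((c, c, i))
            i += 1
        else:
            if not buf:
                buf_start = i
            buf.append(c)
            i += 1
    flush(n)
    return out


def tokenize_iupac(s: str) -> list[tuple[str, str]]:
    """Tokenize an IUPAC-condensed glycan into (token, kind) pairs.

    Kinds are ``"monosaccharide"`` or ``"linkage"``; branch brackets are
    consumed, tokens come out in left-to-right textual order.  Any
    bracket-free run between linkages is treated as a single
    monosaccharide token (so modified sugars like ``GlcNAc6S`` stay whole).

    Raises
    ------
    GlycanParseError
        On empty input, empty tokens or unbalanced brackets/parentheses.
    """
    s = normalize_iupac(s)
    if not s:
        raise GlycanParseError("empty glycan string", 0)
    depth = 0
    for pos, c in enumerate(s):
        if c == "[":
            depth += 1
        elif c == "]":
            depth -= 1
            if depth < 0:
                raise GlycanParseError("unmatched ']'", pos)
    if depth != 0:
        raise GlycanParseError("unbalanced '['", len(s) - 1)
    return [(tok, kind) for tok, kind, _ in _lex(s) if kind in (MONOSACCHARIDE, LINKAGE)]


@dataclass
class GlycanGraph:
    """A glycan as an undirected tree over monosaccharide and linkage nodes.

    ``edges`` hold each unordered pair once; consumers doing directed
    message passing expand both directions.  ``parent_of`` records, for
    every linkage node, its (child_mono, parent_mono) orientation toward
    the reducing end (parent may be ``None`` for a dangling linkage).
    """

    node_labels: list[str]
    node_kinds: list[str]
    edges: list[tuple[int, int]]
    source: str
    parent_of: dict[int, tuple[int, int | None]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def degree(self) -> list[int]:
        d = [0] * self.n_nodes
        for u, v in self.edges:
            d[u] += 1
            d[v] += 1
        return d

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for i, (lab, kind) in enumerate(zip(self.node_labels, self.node_kinds)):
            g.add_node(i, label=lab, kind=kind)
        g.add_edges_from(self.edges)
        return g


def glycan_to_graph(s: str, vocab: "Vocabulary | None" = None) -> GlycanGraph:
    """Convert an IUPAC-condensed string to a :class:`GlycanGraph`.

    Each token becomes one node in textual order.  A linkage node gets an
    edge to the monosaccharide it follows and, via a bracket-aware stack,
    to the monosaccharide it attaches to.  A trailing unclosed linkage
    (Tn antigen style) stays as a degree-1 node.
    """
    norm = normalize_iupac(s)
    if not norm:
        raise GlycanParseError("empty glycan string", 0)
    depth = 0
    for pos, c in enumerate(norm):
        if c == "[":
            depth += 1
        elif c == "]":
            depth -= 1
            if depth < 0:
                raise GlycanParseError("unmatched ']'", pos)
    if depth != 0:
        raise GlycanParseError("unbalanced '['", len(norm) - 1)

    tokens = _lex(norm)
    dangling = norm and not tokens[-1][0] in "[]" and not norm.endswith(")") \
        and tokens[-1][1] == LINKAGE
    labels: list[str] = []
    kinds: list[str] = []
    edges: list[tuple[int, int]] = []
    parent_of: dict[int, tuple[int, int | None]] = {}

    pending: list[int] = []        # linkage nodes awaiting their parent mono
    stack: list[list[int]] = []    # saved pending lists of outer branch levels
    last_mono: int | None = None   # mono that a following linkage hangs off
    for tok, kind, pos in tokens:
        if kind == "[":
            stack.append(pending)
            pending = []
            last_mono = None
        elif kind == "]":
            if not pending:
                raise GlycanParseError("branch does not end in a linkage", pos)
            outer = stack.pop()
            pending = outer + pending
            last_mono = None
        elif kind == MONOSACCHARIDE:
            if last_mono is not None:
                raise GlycanParseError("two monosaccharides without a linkage", pos)
            idx = len(labels)
            labels.append(tok)
            kinds.append(MONOSACCHARIDE)
            for link in pending:
                edges.append((link, idx))
                child, _ = parent_of[link]
                parent_of[link] = (child, idx)
            pending = []
            last_mono = idx
        else:  # linkage
            if last_mono is None:
                raise GlycanParseError("linkage with no preceding monosaccharide", pos)
            idx = len(labels)
            labels.append(tok)
            kinds.append(LINKAGE)
            edges.append((last_mono, idx))
            parent_of[idx] = (last_mono, None)
            pending = [idx]
            last_mono = None
    if pending and not dangling:
        raise GlycanParseError("linkage has no attachment target", len(norm) - 1)
    if not labels:
        raise GlycanParseError("empty glycan string", 0)
    return GlycanGraph(labels, kinds, edges, source=s, parent_of=parent_of)


@dataclass(frozen=True)
class Vocabulary:
    """Stable bijection token -> index with trailing ``<mask>``/``<unk>`` slots."""

    token_to_index: dict[str, int]

    @property
    def mask_index(self) -> int:
        return self.token_to_index[MASK_TOKEN]

    @property
    def unk_index(self) -> int:
        return self.token_to_index[UNK_TOKEN]

    def __len__(self) -> int:
        return len(self.token_to_index)

    def __getitem__(self, token: str) -> int:
        return self.token_to_index.get(token, self.token_to_index[UNK_TOKEN])

    def index_to_token(self) -> list[str]:
        out = [""] * len(self.token_to_index)
        for t, i in self.token_to_index.items():
            out[i] = t
        return out

    def encode_graph(self, g: GlycanGraph) -> list[int]:
        return [self[t] for t in g.node_labels]


def build_vocabulary(glycans: Iterable[str]) -> Vocabulary:
    """Build a vocabulary over every token in the corpus (sorted, deterministic)."""
    tokens: set[str] = set()
    n = 0
    for s in glycans:
        n += 1
        for tok, _ in tokenize_iupac(s):
            tokens.add(tok)
    if n == 0:
        raise ValueError("empty glycan corpus")
    mapping = {t: i for i, t in enumerate(sorted(tokens))}
    mapping[MASK_TOKEN] = len(mapping)
    mapping[UNK_TOKEN] = len(mapping)
    return Vocabulary(mapping)


def extract_motifs(s: str, max_len: int = 3) -> Counter:
    """Multiset of mono-, di- and tri-saccharide motifs of a glycan.

    A motif of length k is a linear chain of k monosaccharides with their
    intervening linkages, written non-reducing -> reducing end (IUPAC
    reading order), e.g. ``Neu5Ac(a2-3)Gal``.  Dangling linkages
    contribute no k>=2 motifs.
    """
    if not 1 <= max_len <= 3:
        raise ValueError("max_len must be in 1..3")
    g = glycan_to_graph(s)
    motifs: Counter = Counter()
    monos = [i for i, k in enumerate(g.node_kinds) if k == MONOSACCHARIDE]
    for i in monos:
        motifs[g.node_labels[i]] += 1
    if max_len == 1:
        return motifs
    # child --linkage--> parent steps toward the reducing end
    steps: list[tuple[int, int, int]] = []
    for link, (child, parent) in g.parent_of.items():
        if parent is not None:
            steps.append((child, link, parent))
    lab = g.node_labels
    for child, link, parent in steps:
        motifs[f"{lab[child]}({lab[link]}){lab[parent]}"] += 1
    if max_len == 3:
        by_child = {}
        for child, link, parent in steps:
            by_child.setdefault(child, []).append((link, parent))
        for child, link, parent in steps:
            for link2, parent2 in by_child.get(parent, []):
                motifs[
                    f"{lab[child]}({lab[link]}){lab[parent]}({lab[link2]}){lab[parent2]}"
                ] += 1
    return motifs


def motif_count_vector(s: str, motif_index: Sequence[str], max_len: int = 3):
    """Integer count vector of `s` over a fixed ordered motif list."""
    import numpy as np

    counts = extract_motifs(s, max_len=max_len)
    return np.array([counts.get(m, 0) for m in motif_index], dtype=np.int64)
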