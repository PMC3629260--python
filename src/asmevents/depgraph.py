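"""Sentence-level dependency graphs.

A sentence is modelled as a labeled, directed multigraph: nodes are tokens
(1-based sentence positions) and edges are governor→dependent grammatical
relations such as ``nsubj`` or, in the collapsed Stanford dialect,
``prep_to``.  Collapsed dependencies routinely produce parallel edges,
cycles and disconnected function words, all of which are permitted here.

Shortest-path machinery always operates on the *undirected* view of the
graph; edge direction is scored separately during matching.  Parallel edges
count as distinct length-1 connections, so two tokens joined by both an
``nsubj`` and an ``rcmod`` edge are linked by two distinct shortest paths.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import networkx as nx

from .errors import GraphLookupError, IntegrityError, ParseError

#: Node-index offset used to materialize collapsed-dependency copy tokens
#: (``word-6'``) as distinct nodes.  A token printed with k trailing
#: apostrophes is stored at ``index + k * COPY_OFFSET``.
COPY_OFFSET = 10_000


@dataclass
class Token:
    """A dependency-graph node: one token of the sentence.

    ``is_entity`` marks the token as a masked biological entity
    (``BIO_Entity``).  Masking is virtual: the original surface/lemma/POS are
    retained for reporting, and the matcher simply skips lexical features for
    entity nodes.
    """

    index: int
    surface: str
    lemma: str = ""
    pos: str = ""
    is_entity: bool = False
    entity_ref: Optional[str] = None
    is_trigger: bool = False
    start: Optional[int] = None  # character offset into the document text
    end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise IntegrityError(f"token index must be >= 1, got {self.index}")
        if not self.surface:
            raise IntegrityError(f"token {self.index} has an empty surface form")


@dataclass(frozen=True)
class DepEdge:
    """A directed governor→dependent dependency with a relation label."""

    governor: int
    dependent: int
    label: str

    def __post_init__(self) -> None:
        if not self.label:
            raise IntegrityError("dependency edge with empty label")


@dataclass(frozen=True)
class Path:
    """An undirected path: the node sequence plus the concrete edge used at
    each hop (needed to tell parallel edges apart)."""

    nodes: tuple[int, ...]
    edges: tuple[DepEdge, ...]

    def __len__(self) -> int:  # path length = number of edges
        return len(self.edges)

    def sort_key(self):
        return (self.nodes, tuple(e.label for e in self.edges),
                tuple((e.governor, e.dependent) for e in self.edges))


class DepGraph:
    """Labeled directed dependency multigraph of one sentence."""

    def __init__(self, sentence_id: str = "", tokens: Iterable[Token] = (),
                 edges: Iterable[DepEdge] = ()):
        self.sentence_id = sentence_id
        self.tokens: dict[int, Token] = {}
        self.edges: list[DepEdge] = []
        self._und: Optional[nx.MultiGraph] = None
        self._splen: dict[int, dict[int, int]] = {}
        for t in tokens:
            self.add_token(t)
        for e in edges:
            self.add_edge(e)

    # -- construction -------------------------------------------------------

    def add_token(self, token: Token) -> None:
        old = self.tokens.get(token.index)
        if old is not None and old.surface != token.surface:
            raise IntegrityError(
                f"token index {token.index} bound to both "
                f"{old.surface!r} and {token.surface!r}")
        if old is None:
            self.tokens[token.index] = token
            self._invalidate()

    def add_edge(self, edge: DepEdge) -> None:
        for end in (edge.governor, edge.dependent):
            if end not in self.tokens:
                raise IntegrityError(
                    f"edge {edge.label}({edge.governor},{edge.dependent}) "
                    f"references missing token {end}")
        self.edges.append(edge)
        self._invalidate()

    def _invalidate(self) -> None:
        self._und = None
        self._splen = {}

    # -- views --------------------------------------------------------------

    def __contains__(self, index: int) -> bool:
        return index in self.tokens

    def __len__(self) -> int:
        return len(self.tokens)

    def node_indices(self) -> list[int]:
        return sorted(self.tokens)

    def token(self, index: int) -> Token:
        try:
            return self.tokens[index]
        except KeyError:
            raise GraphLookupError(f"no token with index {index} in "
                                   f"sentence {self.sentence_id!r}") from None

    def entity_indices(self) -> list[int]:
        return sorted(i for i, t in self.tokens.items() if t.is_entity)

    def undirected(self) -> nx.MultiGraph:
        """Undirected multigraph view; every directed edge contributes one
        undirected connection (parallel edges preserved)."""
        if self._und is None:
            g = nx.MultiGraph()
            g.add_nodes_from(self.tokens)
            for e in self.edges:
                g.add_edge(e.governor, e.dependent, edge=e)
            self._und = g
        return self._und

    # -- shortest paths -----------------------------------------------------

    def shortest_path_length(self, u: int, v: int) -> Optional[int]:
        """Length of the shortest undirected path, ``None`` if disconnected."""
        for i in (u, v):
            if i not in self.tokens:
                raise GraphLookupError(f"no token with index {i}")
        if u not in self._splen:
            self._splen[u] = dict(
                nx.single_source_shortest_path_length(self.undirected(), u))
        return self._splen[u].get(v)

    def all_shortest_paths(self, u: int, v: int) -> list[Path]:
        """All shortest undirected paths between two tokens.

        Exhaustive over parallel edges: each distinct edge at each hop gives
        a distinct path.  Returns the single zero-length path when ``u == v``
        and the empty list when the tokens are disconnected.
        """
        for i in (u, v):
            if i not in self.tokens:
                raise GraphLookupError(f"no token with index {i}")
        if u == v:
            return [Path((u,), ())]
        und = self.undirected()
        try:
            node_paths = list(nx.all_shortest_paths(und, u, v))
        except nx.NetworkXNoPath:
            return []
        out: list[Path] = []
        for seq in node_paths:
            hop_choices: list[list[DepEdge]] = []
            for a, b in zip(seq, seq[1:]):
                hop_choices.append(sorted(
                    (d["edge"] for d in und[a][b].values()),
                    key=lambda e: (e.label, e.governor, e.dependent)))
            for combo in itertools.product(*hop_choices):
                out.append(Path(tuple(seq), tuple(combo)))
        out.sort(key=Path.sort_key)
        return out


def all_shortest_paths(g: DepGraph, u: int, v: int) -> list[Path]:
    return g.all_shortest_paths(u, v)


def shortest_path_length(g: DepGraph, u: int, v: int) -> Optional[int]:
    return g.shortest_path_length(u, v)


def path_union(g: DepGraph, paths: Iterable[Path]) -> DepGraph:
    """Subgraph of ``g`` containing exactly the nodes and original directed,
    labeled edges traversed by any of the given paths."""
    nodes: set[int] = set()
    edges: list[DepEdge] = []
    seen: set[DepEdge] = set()
    for p in paths:
        for n in p.nodes:
            if n not in g:
                raise GraphLookupError(f"path node {n} not in graph")
            nodes.add(n)
        for e in p.edges:
            if e not in seen:
                seen.add(e)
                edges.append(e)
    sub = DepGraph(sentence_id=g.sentence_id)
    for n in sorted(nodes):
        sub.add_token(replace(g.token(n)))
    for e in edges:
        sub.add_edge(e)
    return sub


def generalize_entities(g: DepGraph,
                        entities: Sequence[tuple[str, int]]) -> DepGraph:
    """Flag entity head tokens as ``BIO_Entity``.

    Returns a new graph in which the given tokens have ``is_entity=True``
    (the matcher then ignores their lexical features); original surfaces are
    retained for reporting.  Idempotent.
    """
    for _, head in entities:
        if head not in g:
            raise GraphLookupError(f"entity head token {head} not in graph")
    flagged = {head: eid for eid, head in entities}
    out = DepGraph(sentence_id=g.sentence_id)
    for i in g.node_indices():
        t = replace(g.token(i))
        if i in flagged:
            t.is_entity = True
            t.entity_ref = flagged[i]
        out.add_token(t)
    for e in g.edges:
        out.add_edge(e)
    return out


# -- parse-format readers ---------------------------------------------------

_SD_LINE = re.compile(r"^\s*([^\s(]+)\(\s*(.+?)\s*,\s*(.+?)\s*\)\s*$")
_SD_TOKEN = re.compile(r"^(.+)-(\d+)('*)$")


def _sd_token(text: str, lineno: int) -> tuple[str, int]:
    m = _SD_TOKEN.match(text)
    if not m:
        raise ParseError(f"line {lineno}: cannot parse token {text!r} "
                         "(expected form-index)")
    surface, idx, copies = m.group(1), int(m.group(2)), m.group(3)
    return surface, idx + COPY_OFFSET * len(copies)


def parse_sd(text: str | Iterable[str],
             token_table: Optional[dict[int, tuple[str, str, str]]] = None,
             sentence_id: str = "") -> DepGraph:
    """Read Stanford-dependency triples, one ``label(word-i, word-j)`` per line.

    Copy tokens marked with trailing apostrophes (``word-6'``) become
    distinct nodes at ``index + COPY_OFFSET``.  An optional ``token_table``
    maps token index to ``(surface, lemma, pos)`` and supplies the lexical
    features the triple dialect itself lacks.
    """
    lines = text.splitlines() if isinstance(text, str) else list(text)
    g = DepGraph(sentence_id=sentence_id)
    if token_table:
        # the sidecar lists every token, including ones no dependency touches
        for idx in sorted(token_table):
            surface, lemma, pos = token_table[idx]
            g.add_token(Token(index=idx, surface=surface, lemma=lemma, pos=pos))
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        m = _SD_LINE.match(line)
        if not m:
            raise ParseError(f"line {lineno}: malformed dependency {raw!r}")
        label = m.group(1)
        gov_surface, gov_idx = _sd_token(m.group(2), lineno)
        dep_surface, dep_idx = _sd_token(m.group(3), lineno)
        for surface, idx in ((gov_surface, gov_idx), (dep_surface, dep_idx)):
            lemma = pos = ""
            if token_table and idx % COPY_OFFSET in token_table:
                _, lemma, pos = token_table[idx % COPY_OFFSET]
            g.add_token(Token(index=idx, surface=surface, lemma=lemma, pos=pos))
        g.add_edge(DepEdge(governor=gov_idx, dependent=dep_idx, label=label))
    return g


def parse_token_table(text: str) -> dict[int, tuple[str, str, str]]:
    """Sidecar token table: ``index<TAB>surface<TAB>lemma<TAB>POS`` lines."""
    table: dict[int, tuple[str, str, str]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise ParseError(f"line {lineno}: expected 4 tab-separated "
                             f"columns, got {len(cols)}")
        try:
            idx = int(cols[0])
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer index {cols[0]!r}")
        table[idx] = (cols[1], cols[2], cols[3])
    return table


def parse_conll(lines: str | Iterable[str], sentence_id: str = "") -> DepGraph:
    """Read one sentence of CoNLL-X / CoNLL-U rows.

    Accepts the full 10-column layouts (ID FORM LEMMA ... HEAD DEPREL) as
    well as a compact 6-column ``ID FORM LEMMA POS HEAD DEPREL`` layout.
    ``HEAD=0`` rows (the root) produce no edge; comment lines and multi-word
    ``i-j`` range rows are skipped.
    """
    rows = lines.splitlines() if isinstance(lines, str) else list(lines)
    g = DepGraph(sentence_id=sentence_id)
    pending: list[tuple[int, int, str, int]] = []  # head, dep, label, lineno
    for lineno, raw in enumerate(rows, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if "-" in cols[0] or "." in cols[0]:
            continue  # multiword range / empty node rows
        if len(cols) >= 10:
            id_s, form, lemma, pos, head_s, deprel = (
                cols[0], cols[1], cols[2],
                cols[4] if cols[4] != "_" else cols[3], cols[6], cols[7])
        elif len(cols) == 6:
            id_s, form, lemma, pos, head_s, deprel = cols
        else:
            raise ParseError(f"line {lineno}: expected 6 or >=10 columns, "
                             f"got {len(cols)}")
        try:
            idx = int(id_s)
            head = int(head_s)
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer ID/HEAD in {raw!r}")
        g.add_token(Token(index=idx, surface=form, lemma=lemma, pos=pos))
        if head != 0:
            pending.append((head, idx, deprel, lineno))
    for head, dep, label, lineno in pending:
        if head not in g:
            raise IntegrityError(f"line {lineno}: HEAD {head} references an "
                                 "absent token")
        g.add_edge(DepEdge(governor=head, dependent=dep, label=label))
    return g
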