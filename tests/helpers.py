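"""Shared test apparatus: hand-built annotated documents, independent
brute-force oracles for the matcher, and a seeded random-instance
generator for rule/sentence pairs."""

from __future__ import annotations

import itertools
from typing import Optional

import numpy as np

from asmevents.asm import MatchCriteria, match_node
from asmevents.depgraph import DepEdge, DepGraph, Token
from asmevents.rules import EventRule
from asmevents.standoff import (AnnotatedDocument, EntityAnn, EventAnn,
                                TriggerAnn)

# -- document builder -------------------------------------------------------

def make_doc(doc_id, sentences):
    """Build an AnnotatedDocument from compact sentence specs.

    Each sentence spec is a dict with keys:
      tokens   : list of (surface, pos) or (surface, pos, lemma)
      edges    : list of (gov, dep, label)
      entities : {tid: token_index}
      triggers : {tid: (event_type, token_index)}
      events   : list of (eid, event_type, trigger_tid, [(role, ref)])
    """
    doc = AnnotatedDocument(doc_id=doc_id, text="")
    pieces, off = [], 0
    graphs = []
    for si, spec in enumerate(sentences):
        g = DepGraph(sentence_id=f"{doc_id}.s{si}")
        for i, tok in enumerate(spec["tokens"], start=1):
            surface, pos = tok[0], tok[1]
            lemma = tok[2] if len(tok) > 2 else surface.lower()
            g.add_token(Token(i, surface, lemma, pos,
                              start=off, end=off + len(surface)))
            pieces.append(surface)
            off += len(surface) + 1
        for gov, dep, label in spec.get("edges", []):
            g.add_edge(DepEdge(gov, dep, label))
        graphs.append(g)
    doc.text = " ".join(pieces)
    doc.sentences = graphs
    for si, spec in enumerate(sentences):
        g = graphs[si]
        for tid, tok_idx in spec.get("entities", {}).items():
            t = g.token(tok_idx)
            doc.entities[tid] = EntityAnn(tid, "Protein", t.start, t.end,
                                          t.surface, si, tok_idx, (tok_idx,))
        for tid, (etype, tok_idx) in spec.get("triggers", {}).items():
            t = g.token(tok_idx)
            doc.triggers[tid] = TriggerAnn(tid, etype, t.start, t.end,
                                           t.surface, si, (tok_idx,))
        for eid, etype, trig_tid, args in spec.get("events", []):
            resolved = [(role,
                         doc.entities[ref] if ref in doc.entities
                         else doc.events[ref])
                        for role, ref in args]
            doc.events[eid] = EventAnn(eid, etype, doc.triggers[trig_tid],
                                       resolved)
    return doc


# -- independent shortest-path machinery (oracle side) ----------------------

def oracle_adjacency(g: DepGraph):
    adj: dict[int, list[tuple[int, DepEdge]]] = {i: [] for i in g.tokens}
    for e in g.edges:
        adj[e.governor].append((e.dependent, e))
        adj[e.dependent].append((e.governor, e))
    return adj


def oracle_bfs(g: DepGraph, src: int) -> dict[int, int]:
    adj = oracle_adjacency(g)
    dist = {src: 0}
    frontier = [src]
    while frontier:
        nxt = []
        for u in frontier:
            for v, _ in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def oracle_shortest_paths(g: DepGraph, u: int, v: int):
    """Exhaustive shortest undirected paths as (node tuple, edge tuple),
    every parallel edge counted separately.  Independent DFS enumeration."""
    if u == v:
        return [((u,), ())]
    du = oracle_bfs(g, u)
    dv = oracle_bfs(g, v)
    if v not in du:
        return []
    d = du[v]
    adj = oracle_adjacency(g)
    out = []

    def walk(cur, nodes, edges):
        if cur == v:
            out.append((tuple(nodes), tuple(edges)))
            return
        for nxt, e in adj[cur]:
            if (du.get(nxt) == du[cur] + 1
                    and dv.get(nxt, -1) == d - du[cur] - 1):
                walk(nxt, nodes + [nxt], edges + [e])

    walk(u, [u], [])
    return out


def _labels(edges) -> dict:
    c: dict[str, int] = {}
    for e in edges:
        c[e.label] = c.get(e.label, 0) + 1
    return c


def _dirs(nodes, edges) -> dict:
    c = {"f": 0, "b": 0}
    for i, e in enumerate(edges):
        if e.governor == nodes[i] and e.dependent == nodes[i + 1]:
            c["f"] += 1
        else:
            c["b"] += 1
    return c


# -- brute-force oracles ----------------------------------------------------

def brute_force_mappings(rule: EventRule, sentence: DepGraph,
                         criteria: MatchCriteria,
                         lexicon: Optional[frozenset] = None):
    """Every injective, feature-compatible rule→sentence assignment, by
    exhaustive Cartesian product (independent of the recursive matcher)."""
    nodes = sorted(rule.graph.tokens)
    cands = [[s for s in sentence.node_indices()
              if match_node(rule.graph.token(rn), sentence.token(s),
                            criteria, lexicon)]
             for rn in nodes]
    out = []
    for combo in itertools.product(*cands):
        if len(set(combo)) == len(combo):
            out.append(dict(zip(nodes, combo)))
    return out


def is_exact_embedding(rule: EventRule, sentence: DepGraph,
                       mapping: dict[int, int]) -> bool:
    """Does the mapping preserve, for every unordered rule-node pair, the
    shortest-path length, and admit shortest paths with identical label and
    orientation multisets?  (The distance-preserving reading of an exact
    match.)"""
    nodes = sorted(rule.graph.tokens)
    for i, u in enumerate(nodes):
        du_r = oracle_bfs(rule.graph, u)
        du_s = oracle_bfs(sentence, mapping[u])
        for v in nodes[i + 1:]:
            if v not in du_r:
                return False  # rule graphs are connected; defensive
            if du_s.get(mapping[v]) != du_r[v]:
                return False
            rps = oracle_shortest_paths(rule.graph, u, v)
            sps = oracle_shortest_paths(sentence, mapping[u], mapping[v])
            ok = any(
                _labels(rp_e) == _labels(sp_e)
                and _dirs(rp_n, rp_e) == _dirs(sp_n, sp_e)
                for rp_n, rp_e in rps for sp_n, sp_e in sps)
            if not ok:
                return False
    return True


def brute_force_exact_matches(rule: EventRule, sentence: DepGraph,
                              criteria: MatchCriteria):
    """All injective feature-compatible mappings that are exact (distance-,
    label- and orientation-preserving) embeddings."""
    return [m for m in brute_force_mappings(rule, sentence, criteria)
            if is_exact_embedding(rule, sentence, m)]


# -- random instances -------------------------------------------------------

_LEMMAS = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta",
           "theta", "iota", "kappa"]
_POS = ["NN", "NNS", "VBZ", "VB", "JJ"]
_LABELS = ["nsubj", "dobj", "prep_of", "prep_in", "nn", "amod"]


def random_instance(rng: np.random.Generator,
                    max_rule: int = 8, max_sentence: int = 25
                    ) -> tuple[EventRule, DepGraph]:
    """A random sentence graph and a rule graph to match against it.

    The sentence is a random tree plus a few extra (possibly parallel)
    edges; most rules are sampled as connected sentence subgraphs (so exact
    matches exist), then lightly mutated with some probability to create
    near-misses.
    """
    n = int(rng.integers(6, max_sentence + 1))
    sent = DepGraph(sentence_id="rand")
    for i in range(1, n + 1):
        sent.add_token(Token(i, str(rng.choice(_LEMMAS)),
                             pos=str(rng.choice(_POS)),
                             lemma="", is_entity=bool(rng.random() < 0.15)))
        tok = sent.token(i)
        tok.lemma = tok.surface
    for i in range(2, n + 1):
        j = int(rng.integers(1, i))
        gov, dep = (i, j) if rng.random() < 0.5 else (j, i)
        sent.add_edge(DepEdge(gov, dep, str(rng.choice(_LABELS))))
    for _ in range(int(rng.integers(0, 4))):
        a, b = rng.choice(np.arange(1, n + 1), size=2, replace=False)
        sent.add_edge(DepEdge(int(a), int(b), str(rng.choice(_LABELS))))

    k = int(rng.integers(2, max_rule + 1))
    if rng.random() < 0.75:
        # connected subgraph sample: random growth along sentence edges
        start = int(rng.integers(1, n + 1))
        chosen = {start}
        frontier_edges = list(sent.edges)
        for _ in range(4 * n):
            if len(chosen) >= k:
                break
            candidates = [e for e in frontier_edges
                          if (e.governor in chosen) != (e.dependent in chosen)]
            if not candidates:
                break
            e = candidates[int(rng.integers(0, len(candidates)))]
            chosen.add(e.governor)
            chosen.add(e.dependent)
        rg = DepGraph(sentence_id="rule")
        for i in sorted(chosen):
            t = sent.token(i)
            rg.add_token(Token(i, t.surface, t.lemma, t.pos,
                               is_entity=t.is_entity))
        for e in sent.edges:
            if e.governor in chosen and e.dependent in chosen:
                rg.add_edge(DepEdge(e.governor, e.dependent, e.label))
        if rng.random() < 0.3 and rg.edges:
            # mutate one edge label to create near-misses
            i = int(rng.integers(0, len(rg.edges)))
            e = rg.edges[i]
            rg.edges[i] = DepEdge(e.governor, e.dependent,
                                  str(rng.choice(_LABELS)))
            rg._invalidate()
    else:
        rg = DepGraph(sentence_id="rule")
        for i in range(1, k + 1):
            rg.add_token(Token(i, str(rng.choice(_LEMMAS)),
                               pos=str(rng.choice(_POS)), lemma="x",
                               is_entity=bool(rng.random() < 0.15)))
            tok = rg.token(i)
            tok.lemma = tok.surface
        for i in range(2, k + 1):
            j = int(rng.integers(1, i))
            gov, dep = (i, j) if rng.random() < 0.5 else (j, i)
            rg.add_edge(DepEdge(gov, dep, str(rng.choice(_LABELS))))
    rule = EventRule(rule_id="rnd", event_type="X", graph=rg,
                     trigger_nodes=frozenset({min(rg.tokens)}),
                     slots=(), variant="individual")
    return rule, sent


# -- nested-propagation pruning fixture -------------------------------------

_FIX_LEMMA = {"productions": "production", "expressions": "expression",
              "Expression": "expression"}


def _lex(surface):
    return (surface, "NNS" if surface.endswith("s") and surface[0].islower()
            else "NN", _FIX_LEMMA.get(surface, surface.lower()))


def propagation_corpus():
    """A training corpus where pruning one unreliable simple rule strips a
    dependent regulation rule of its true positives, so the regulation rule
    falls below the ratio threshold only in the next iteration.

    Layout (one sentence per document):
      d0/d1   gold regulation over a 'production(s)' expression event
              (surface variation defeats rule dedup, so each rule still
              gets scored on the other document);
      dx0..4  unannotated 'production of X' contexts: false positives that
              doom the production rules in iteration 1;
      d6/d7   reliable 'expression(s) of X' gold events;
      d80/d81 'induces Expression of X' with gold expression but no
              regulation: standing false positives for regulation rules.
    """
    docs = []

    def reg_doc(doc_id, cause, trigger_noun, theme):
        return make_doc(doc_id, [{
            "tokens": [_lex(cause), ("induces", "VBZ", "induce"),
                       _lex(trigger_noun), ("of", "IN"), _lex(theme)],
            "edges": [(2, 1, "nsubj"), (2, 3, "dobj"), (3, 5, "prep_of")],
            "entities": {"T1": 1, "T2": 5},
            "triggers": {"T3": ("Gene_expression", 3),
                         "T4": ("Positive_regulation", 2)},
            "events": [("E1", "Gene_expression", "T3", [("Theme", "T2")]),
                       ("E2", "Positive_regulation", "T4",
                        [("Theme", "E1"), ("Cause", "T1")])],
        }])

    docs.append(reg_doc("d0", "PROTa", "production", "PROTb"))
    docs.append(reg_doc("d1", "PROTc", "productions", "PROTd"))
    for k in range(5):
        docs.append(make_doc(f"dx{k}", [{
            "tokens": [("production", "NN"), ("of", "IN"),
                       (f"PROTx{k}", "NN")],
            "edges": [(1, 3, "prep_of")],
            "entities": {"T1": 3},
        }]))
    for doc_id, trig, theme in (("d6", "expression", "PROTe"),
                                ("d7", "expressions", "PROTf")):
        docs.append(make_doc(doc_id, [{
            "tokens": [_lex(trig), ("of", "IN"), (theme, "NN")],
            "edges": [(1, 3, "prep_of")],
            "entities": {"T1": 3},
            "triggers": {"T2": ("Gene_expression", 1)},
            "events": [("E1", "Gene_expression", "T2", [("Theme", "T1")])],
        }]))
    for doc_id, cause, theme in (("d80", "PROTg", "PROTh"),
                                 ("d81", "PROTi", "PROTj")):
        docs.append(make_doc(doc_id, [{
            "tokens": [(cause, "NN"), ("induces", "VBZ", "induce"),
                       _lex("Expression"), ("of", "IN"), (theme, "NN")],
            "edges": [(2, 1, "nsubj"), (2, 3, "dobj"), (3, 5, "prep_of")],
            "entities": {"T1": 1, "T2": 5},
            "triggers": {"T3": ("Gene_expression", 3)},
            "events": [("E1", "Gene_expression", "T3", [("Theme", "T2")])],
        }]))
    return docs
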