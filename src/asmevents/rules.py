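"""Rule induction: from annotated events to generalized graph rules.

Each annotated event is turned into one or more *event rules*: small
dependency subgraphs connecting the event trigger to its arguments, with
entity argument tokens masked as ``BIO_Entity`` and sub-event arguments
anchored at the sub-event's trigger token.

Two families of rules are produced per event:

* **union** variants — the dependency-path union jointly covering one
  shortest-path choice per argument role (one rule per element of the
  Cartesian product across the roles' shortest-path sets), which identify
  the trigger and all arguments of a complex event simultaneously;
* **individual** variants — one rule per (role, shortest path), which
  determine arguments independently and are later grouped by shared
  trigger.

An event whose trigger-to-cause tokens are linked by two shortest paths and
whose trigger-to-theme tokens are linked by one therefore yields
2 unions + 3 individuals = 5 distinct rules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional, Sequence

from .depgraph import DepEdge, DepGraph, Path, Token, generalize_entities, path_union
from .standoff import AnnotatedDocument, EntityAnn, EventAnn

logger = logging.getLogger(__name__)

ENTITY = "entity"
SUB_EVENT = "sub_event"

#: A path bundle: one shortest-path choice per trigger token (singleton for
#: single-token triggers).  The graph of a bundle is the union of its paths.
PathBundle = tuple[Path, ...]


@dataclass(frozen=True)
class RuleSlot:
    role: str
    node: int
    kind: str  # ENTITY or SUB_EVENT


@dataclass
class EventRule:
    """A generalized event rule: graph fragment + role descriptors."""

    rule_id: str
    event_type: str
    graph: DepGraph
    trigger_nodes: frozenset[int]
    slots: tuple[RuleSlot, ...]
    variant: str  # "union" | "individual"
    provenance: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def sub_event_nodes(self) -> frozenset[int]:
        return frozenset(s.node for s in self.slots if s.kind == SUB_EVENT)

    @property
    def is_complex(self) -> bool:
        return bool(self.sub_event_nodes)

    def canonical_key(self) -> tuple:
        """Order-preserving relabeling of node indices; entity nodes compare
        by their mask, other nodes by stored lexical features."""
        nodes = sorted(self.graph.tokens)
        rank = {n: i for i, n in enumerate(nodes)}
        sub = self.sub_event_nodes
        node_feats = []
        for n in nodes:
            t = self.graph.token(n)
            feats = ("BIO_Entity",) if t.is_entity else (t.surface, t.lemma, t.pos)
            node_feats.append(feats + (n in self.trigger_nodes, n in sub))
        edges = tuple(sorted((rank[e.governor], rank[e.dependent], e.label)
                             for e in self.graph.edges))
        slots = tuple(sorted((s.role, rank[s.node], s.kind) for s in self.slots))
        trig = tuple(sorted(rank[n] for n in self.trigger_nodes))
        return (self.event_type, tuple(node_feats), edges, trig, slots)


@dataclass
class ArgSpec:
    """One argument of an annotated event, anchored to a token."""

    role: str
    token: int
    kind: str  # ENTITY or SUB_EVENT


def argument_paths(g: DepGraph, trigger_tokens: Iterable[int],
                   arg_token: int) -> list[PathBundle]:
    """Shortest-path bundles connecting an event trigger to one argument.

    For a single-token trigger each bundle holds one of the (possibly
    several) shortest trigger↔argument paths.  For multi-token triggers
    every trigger token must reach the argument, and each bundle combines
    one shortest-path choice per trigger token (Cartesian across the
    per-token path sets).  Returns ``[]``, logged, when any trigger token is
    disconnected from the argument.
    """
    triggers = sorted(set(trigger_tokens))
    per_token: list[list[Path]] = []
    for t in triggers:
        paths = g.all_shortest_paths(t, arg_token)
        if not paths:
            logger.info("sentence %s: trigger token %d disconnected from "
                        "argument %d; no rule for this argument",
                        g.sentence_id, t, arg_token)
            return []
        per_token.append(paths)
    bundles: list[PathBundle] = []
    seen: set[tuple] = set()
    for combo in product(*per_token):
        key = tuple(p.sort_key() for p in combo)
        if key not in seen:
            seen.add(key)
            bundles.append(tuple(combo))
    return bundles


def _bundle_is_degenerate(bundle: PathBundle) -> bool:
    return all(len(p) == 0 for p in bundle)


def _build_rule(event_type: str, g: DepGraph, trigger_tokens: Sequence[int],
                chosen: Sequence[tuple[ArgSpec, PathBundle]],
                variant: str) -> EventRule:
    paths = [p for _, bundle in chosen for p in bundle]
    graph = path_union(g, paths)
    for t in trigger_tokens:  # zero-length bundles still contribute the node
        if t not in graph:
            graph.add_token(Token(index=t, surface=g.token(t).surface,
                                  lemma=g.token(t).lemma, pos=g.token(t).pos))
    slots = []
    for spec, _ in chosen:
        if spec.kind == ENTITY:
            tok = graph.token(spec.token)
            tok.is_entity = True
        slots.append(RuleSlot(role=spec.role, node=spec.token, kind=spec.kind))
    for t in trigger_tokens:
        graph.token(t).is_trigger = True
    return EventRule(rule_id="", event_type=event_type, graph=graph,
                     trigger_nodes=frozenset(trigger_tokens),
                     slots=tuple(slots), variant=variant)


def rule_variants(event_type: str, trigger_tokens: Iterable[int],
                  args: Sequence[tuple[ArgSpec, list[PathBundle]]],
                  g: DepGraph) -> list[EventRule]:
    """All union and individual rule variants for one annotated event.

    ``args`` pairs each argument with its shortest-path bundles.  Duplicates
    (identical generalized graph and slot structure) are collapsed; events
    with a single argument yield individual variants only, since a union
    would duplicate them.
    """
    triggers = sorted(set(trigger_tokens))
    usable = [(spec, bundles) for spec, bundles in args if bundles]
    # a trigger=argument collision (zero-length path) only survives when the
    # event has no other argument; single-node graphs carry no context
    if len(usable) > 1:
        filtered = []
        for spec, bundles in usable:
            bundles = [b for b in bundles if not _bundle_is_degenerate(b)]
            if bundles:
                filtered.append((spec, bundles))
        usable = filtered
    if not usable:
        return []

    rules: list[EventRule] = []
    if len(usable) >= 2:
        for combo in product(*[bundles for _, bundles in usable]):
            chosen = [(spec, bundle)
                      for (spec, _), bundle in zip(usable, combo)]
            rules.append(_build_rule(event_type, g, triggers, chosen, "union"))
    for spec, bundles in usable:
        for bundle in bundles:
            rules.append(_build_rule(event_type, g, triggers,
                                     [(spec, bundle)], "individual"))

    out: list[EventRule] = []
    seen: set[tuple] = set()
    for r in rules:
        key = r.canonical_key()
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def _event_arg_specs(ev: EventAnn) -> list[ArgSpec]:
    specs = []
    for role, filler in ev.args:
        if isinstance(filler, EntityAnn):
            if filler.head_token is None:
                continue
            specs.append(ArgSpec(role=role, token=filler.head_token,
                                 kind=ENTITY))
        else:  # nested event: anchor at the sub-event's trigger head
            head = filler.trigger.head_token
            if head is None:
                continue
            specs.append(ArgSpec(role=role, token=head, kind=SUB_EVENT))
    return specs


def rules_for_event(g: DepGraph, event_type: str,
                    trigger_tokens: Iterable[int],
                    args: Sequence[ArgSpec]) -> list[EventRule]:
    """Induce the rules of one event given token-level anchors."""
    triggers = sorted(set(trigger_tokens))
    with_paths = [(spec, argument_paths(g, triggers, spec.token))
                  for spec in args]
    return rule_variants(event_type, triggers, with_paths, g)


def induce_rules(doc: AnnotatedDocument) -> list[EventRule]:
    """All rules of one annotated document (deduplicated within it)."""
    rules: list[EventRule] = []
    for si, g in enumerate(doc.sentences):
        gg = generalize_entities(g, doc.sentence_entities(si))
        for ev in doc.sentence_events(si):
            triggers = [t for t in ev.trigger.tokens if t in gg]
            if not triggers:
                logger.warning("%s: trigger of %s not anchored; skipped",
                               doc.doc_id, ev.id)
                continue
            for r in rules_for_event(gg, ev.event_type, triggers,
                                     _event_arg_specs(ev)):
                r.provenance = [(doc.doc_id, g.sentence_id, ev.id)]
                rules.append(r)
    return _dedup(rules)


def induce_corpus(docs: Iterable[AnnotatedDocument]) -> list[EventRule]:
    """Corpus-wide rule induction with deduplication on the canonical graph
    form; all provenances of a duplicated rule are retained."""
    rules: list[EventRule] = []
    for doc in docs:
        rules.extend(induce_rules(doc))
    rules = _dedup(rules)
    for i, r in enumerate(rules, start=1):
        r.rule_id = f"r{i:05d}"
    return rules


def _dedup(rules: list[EventRule]) -> list[EventRule]:
    by_key: dict[tuple, EventRule] = {}
    for r in rules:
        key = r.canonical_key()
        if key in by_key:
            for prov in r.provenance:
                if prov not in by_key[key].provenance:
                    by_key[key].provenance.append(prov)
        else:
            by_key[key] = r
    return list(by_key.values())


def build_trigger_lexicon(docs: Iterable[AnnotatedDocument]) -> frozenset[str]:
    """Lemmas (lowercased; surface fallback) of all annotated event
    triggers — the lexicon behind the known-trigger matching feature."""
    lemmas: set[str] = set()
    for doc in docs:
        for trig in doc.triggers.values():
            if trig.sentence_index is None:
                continue
            g = doc.sentences[trig.sentence_index]
            for t in trig.tokens:
                tok = g.token(t)
                lemmas.add((tok.lemma or tok.surface).lower())
    return frozenset(lemmas)


# -- serialization ----------------------------------------------------------

def rule_to_dict(r: EventRule) -> dict:
    return {
        "rule_id": r.rule_id,
        "event_type": r.event_type,
        "variant": r.variant,
        "nodes": [{"index": t.index, "surface": t.surface, "lemma": t.lemma,
                   "pos": t.pos, "is_entity": t.is_entity,
                   "is_trigger": t.is_trigger}
                  for t in (r.graph.token(i) for i in r.graph.node_indices())],
        "edges": [[e.governor, e.dependent, e.label] for e in r.graph.edges],
        "triggers": sorted(r.trigger_nodes),
        "slots": [[s.role, s.node, s.kind] for s in r.slots],
        "provenance": [list(p) for p in r.provenance],
    }


def rule_from_dict(d: dict) -> EventRule:
    g = DepGraph()
    for n in d["nodes"]:
        g.add_token(Token(index=n["index"], surface=n["surface"],
                          lemma=n["lemma"], pos=n["pos"],
                          is_entity=n["is_entity"],
                          is_trigger=n.get("is_trigger", False)))
    for gov, dep, label in d["edges"]:
        g.add_edge(DepEdge(governor=gov, dependent=dep, label=label))
    return EventRule(
        rule_id=d["rule_id"], event_type=d["event_type"], graph=g,
        trigger_nodes=frozenset(d["triggers"]),
        slots=tuple(RuleSlot(role=r, node=n, kind=k)
                    for r, n, k in d["slots"]),
        variant=d["variant"],
        provenance=[tuple(p) for p in d["provenance"]])


def write_rules_jsonl(rules: Iterable[EventRule], path) -> None:
    with open(path, "w") as fh:
        for r in rules:
            fh.write(json.dumps(rule_to_dict(r), sort_keys=True) + "\n")


def read_rules_jsonl(path) -> list[EventRule]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(rule_from_dict(json.loads(line)))
    return out
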