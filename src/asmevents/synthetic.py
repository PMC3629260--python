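"""Seeded synthetic corpora with planted (nested) events.

The generator emulates the inputs the extraction pipeline consumes —
token sequences with POS and lemma, collapsed-style dependency graphs,
entity annotations and nested gold events — without emulating real
biomedical text distributions or parser error profiles.

Each sentence assembles one or more *facts* (a simple event, or a
regulation wrapping a simple event, with an optional Cause entity),
optional unannotated distractor fragments that reuse event trigger
lemmas in event-like configurations (the raw material for rule pruning),
and function words left unattached.  Sentence graphs are trees over the
content tokens, optionally decorated with parallel edges (a second,
differently-labeled edge between two already-adjacent tokens) so that
multiple shortest paths arise without changing any pairwise distance —
with all perturbation rates at zero, every planted event context is
therefore exactly recoverable by rule matching at threshold 0.

``perturb`` introduces controlled structural noise — node insertions that
lengthen a dependency path by one, edge relabelings, and direction flips
— while leaving gold annotations untouched; it is the stress input for
error-tolerant matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .depgraph import DepEdge, DepGraph, Token
from .errors import ConfigurationError
from .standoff import AnnotatedDocument, EntityAnn, EventAnn, TriggerAnn

ENTITY = "entity"
SUB_EVENT = "sub_event"


@dataclass(frozen=True)
class RoleSpec:
    """One argument slot of a template: the dependency hops from the
    trigger to the argument (label, forward?) with intermediate lemmas,
    plus the function words to realize before the argument."""

    role: str
    kind: str  # ENTITY or SUB_EVENT
    hops: tuple[tuple[str, bool], ...]
    mids: tuple[str, ...] = ()  # lemma per intermediate hop target
    function_words: tuple[str, ...] = ()
    optional: bool = False


@dataclass(frozen=True)
class EventTemplate:
    event_type: str
    trigger_lemmas: tuple[str, ...]
    trigger_pos: str
    roles: tuple[RoleSpec, ...]

    @property
    def is_complex(self) -> bool:
        return any(r.kind == SUB_EVENT for r in self.roles)


def default_templates() -> tuple[EventTemplate, ...]:
    prep_of = RoleSpec("Theme", ENTITY, (("prep_of", True),),
                       function_words=("of",))
    return (
        EventTemplate("Gene_expression", ("expression", "production"), "NN",
                      (prep_of,)),
        EventTemplate("Phosphorylation", ("phosphorylation",), "NN",
                      (prep_of,)),
        EventTemplate("Protein_catabolism", ("degradation",), "NN",
                      (prep_of,)),
        EventTemplate("Transcription", ("transcription",), "NN",
                      (RoleSpec("Theme", ENTITY,
                                (("prep_of", True), ("nn", True)),
                                mids=("gene",), function_words=("of", "the")),)),
        EventTemplate("Localization", ("localization", "secretion"), "NN",
                      (RoleSpec("Theme", ENTITY,
                                (("prep_of", True), ("nn", True)),
                                mids=("protein",),
                                function_words=("of", "the")),)),
        EventTemplate("Binding", ("interaction", "association"), "NN",
                      (RoleSpec("Theme", ENTITY, (("prep_between", True),),
                                function_words=("between",)),
                       RoleSpec("Theme2", ENTITY, (("prep_with", True),),
                                function_words=("and",)))),
        EventTemplate("Positive_regulation", ("induces", "enhances"), "VBZ",
                      (RoleSpec("Theme", SUB_EVENT, (("dobj", True),)),
                       RoleSpec("Cause", ENTITY, (("nsubj", True),),
                                optional=True))),
        EventTemplate("Negative_regulation", ("inhibits", "suppresses"), "VBZ",
                      (RoleSpec("Theme", SUB_EVENT, (("dobj", True),)),
                       RoleSpec("Cause", ENTITY, (("nsubj", True),),
                                optional=True))),
    )


@dataclass
class SynthConfig:
    """Study conditions of the synthetic corpus."""

    n_docs: int = 50
    sentences_per_doc: int = 3
    seed: int = 0
    # perturbation rates, applied per edge (mutually exclusive per edge)
    p_insert: float = 0.0
    p_relabel: float = 0.0
    p_flip: float = 0.0
    distractor_rate: float = 0.2   # per sentence: unannotated event-like fragment
    extra_edge_rate: float = 0.15  # per edge: add a parallel edge
    complex_rate: float = 0.4      # fraction of facts wrapped in a regulation
    cause_rate: float = 0.5        # regulations carrying a Cause entity
    max_facts: int = 2
    entity_pool_size: int = 12
    relabel_pool: tuple[str, ...] = ("prep_in", "prep_on", "amod", "advmod")
    templates: tuple[EventTemplate, ...] = field(default_factory=default_templates)

    def __post_init__(self) -> None:
        for name in ("p_insert", "p_relabel", "p_flip", "distractor_rate",
                     "extra_edge_rate", "complex_rate", "cause_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.p_insert + self.p_relabel + self.p_flip > 1.0:
            raise ConfigurationError("perturbation rates sum above 1")
        if self.n_docs < 0 or self.sentences_per_doc < 1 or self.max_facts < 1:
            raise ConfigurationError("corpus dimensions must be positive")


# -- sentence assembly ------------------------------------------------------

@dataclass
class _TokenDraft:
    surface: str
    lemma: str
    pos: str
    entity: bool = False


@dataclass
class _EventDraft:
    event_type: str
    trigger: int
    args: list[tuple[str, tuple[str, int]]]  # (role, ("ent"|"evt", index))
    annotate: bool


class _SentenceDraft:
    def __init__(self) -> None:
        self.tokens: list[_TokenDraft] = []
        self.edges: list[tuple[int, int, str]] = []
        self.entities: list[tuple[int, str]] = []  # token idx, name
        self.events: list[_EventDraft] = []

    def add(self, surface: str, pos: str, lemma: str = "",
            entity: bool = False) -> int:
        self.tokens.append(_TokenDraft(surface=surface,
                                       lemma=lemma or surface.lower(),
                                       pos=pos, entity=entity))
        return len(self.tokens)  # 1-based


def _simple_templates(cfg: SynthConfig) -> list[EventTemplate]:
    return [t for t in cfg.templates if not t.is_complex]


def _complex_templates(cfg: SynthConfig) -> list[EventTemplate]:
    return [t for t in cfg.templates if t.is_complex]


def _pick(rng: np.random.Generator, seq: Sequence):
    return seq[int(rng.integers(0, len(seq)))]


def _realize(draft: _SentenceDraft, cfg: SynthConfig,
             rng: np.random.Generator, tpl: EventTemplate,
             annotate: bool) -> tuple[int, Optional[int]]:
    """Append one event instance; returns (trigger token, event index)."""
    pending_cause: Optional[RoleSpec] = None
    cause_entity: Optional[int] = None
    roles = list(tpl.roles)
    # an optional Cause is realized before the verb trigger when kept
    if tpl.is_complex:
        cause = next((r for r in roles if r.role == "Cause"), None)
        if cause is not None:
            roles.remove(cause)
            if rng.random() < cfg.cause_rate:
                pending_cause = cause
                name = f"PROT{int(rng.integers(1, cfg.entity_pool_size + 1))}"
                cause_entity = draft.add(name, "NN", entity=True)
                draft.entities.append((cause_entity, name))
    trigger = draft.add(_pick(rng, tpl.trigger_lemmas), tpl.trigger_pos)
    args: list[tuple[str, tuple[str, int]]] = []
    if pending_cause is not None and cause_entity is not None:
        label, forward = pending_cause.hops[0]
        draft.edges.append((trigger, cause_entity, label) if forward
                           else (cause_entity, trigger, label))
        args.append(("Cause", ("ent", cause_entity)))
    for spec in roles:
        for w in spec.function_words:
            draft.add(w, "IN")  # unattached function word
        if spec.kind == SUB_EVENT:
            sub_tpl = _pick(rng, _simple_templates(cfg))
            sub_trig, sub_evt = _realize(draft, cfg, rng, sub_tpl, annotate)
            label, forward = spec.hops[0]
            draft.edges.append((trigger, sub_trig, label) if forward
                               else (sub_trig, trigger, label))
            if sub_evt is not None:
                args.append((spec.role, ("evt", sub_evt)))
        else:
            prev = trigger
            targets: list[int] = []
            for hop_i, (label, forward) in enumerate(spec.hops):
                if hop_i < len(spec.hops) - 1:
                    node = draft.add(spec.mids[hop_i], "NN")
                else:
                    name = f"PROT{int(rng.integers(1, cfg.entity_pool_size + 1))}"
                    node = draft.add(name, "NN", entity=True)
                    draft.entities.append((node, name))
                draft.edges.append((prev, node, label) if forward
                                   else (node, prev, label))
                targets.append(node)
                prev = node
            args.append((spec.role, ("ent", targets[-1])))
    evt_idx: Optional[int] = None
    if annotate:
        draft.events.append(_EventDraft(event_type=tpl.event_type,
                                        trigger=trigger, args=args,
                                        annotate=True))
        evt_idx = len(draft.events) - 1
    return trigger, evt_idx


def _build_sentence(cfg: SynthConfig, rng: np.random.Generator
                    ) -> _SentenceDraft:
    draft = _SentenceDraft()
    n_facts = int(rng.integers(1, cfg.max_facts + 1))
    roots: list[int] = []
    for fi in range(n_facts):
        if fi > 0:
            draft.add("and", "CC")
        if rng.random() < cfg.complex_rate:
            tpl = _pick(rng, _complex_templates(cfg))
        else:
            tpl = _pick(rng, _simple_templates(cfg))
        trigger, _ = _realize(draft, cfg, rng, tpl, annotate=True)
        roots.append(trigger)
    if rng.random() < cfg.distractor_rate:
        draft.add("and", "CC")
        tpl = _pick(rng, _simple_templates(cfg))
        trigger, _ = _realize(draft, cfg, rng, tpl, annotate=False)
        roots.append(trigger)
    for a, b in zip(roots, roots[1:]):
        draft.edges.append((a, b, "conj_and"))
    # parallel edges: a second, reversed connection between already-adjacent
    # tokens (multiple shortest paths, unchanged distances); the alternate
    # label is derived from the base relation so that alternative analyses
    # of different relations never collide
    for gov, dep, label in list(draft.edges):
        if rng.random() < cfg.extra_edge_rate:
            draft.edges.append((dep, gov, f"par_{label}"))
    return draft


# -- document assembly ------------------------------------------------------

def _assemble_document(doc_id: str, drafts: list[_SentenceDraft]
                       ) -> AnnotatedDocument:
    pieces: list[str] = []
    offset = 0
    graphs: list[DepGraph] = []
    doc = AnnotatedDocument(doc_id=doc_id, text="")
    t_counter = 0
    e_counter = 0
    entity_ids: list[list[str]] = []  # per sentence, per draft entity

    for si, draft in enumerate(drafts):
        g = DepGraph(sentence_id=f"{doc_id}.s{si}")
        for i, td in enumerate(draft.tokens, start=1):
            start = offset
            end = start + len(td.surface)
            g.add_token(Token(index=i, surface=td.surface, lemma=td.lemma,
                              pos=td.pos, start=start, end=end))
            pieces.append(td.surface)
            offset = end + 1
        for gov, dep, label in draft.edges:
            g.add_edge(DepEdge(governor=gov, dependent=dep, label=label))
        graphs.append(g)
        ids = []
        for tok_idx, name in draft.entities:
            t_counter += 1
            tid = f"T{t_counter}"
            tok = g.token(tok_idx)
            doc.entities[tid] = EntityAnn(
                id=tid, type="Protein", start=tok.start, end=tok.end,
                text=name, sentence_index=si, head_token=tok_idx,
                tokens=(tok_idx,))
            ids.append(tid)
        entity_ids.append(ids)

    doc.text = " ".join(pieces)
    doc.sentences = graphs

    for si, draft in enumerate(drafts):
        g = graphs[si]
        ent_lookup = {tok_idx: eid for (tok_idx, _), eid
                      in zip(draft.entities, entity_ids[si])}
        local_events: list[EventAnn] = []
        for ed in draft.events:
            t_counter += 1
            tid = f"T{t_counter}"
            tok = g.token(ed.trigger)
            trig = TriggerAnn(id=tid, event_type=ed.event_type,
                              start=tok.start, end=tok.end, text=tok.surface,
                              sentence_index=si, tokens=(ed.trigger,))
            doc.triggers[tid] = trig
            e_counter += 1
            eid = f"E{e_counter}"
            args = []
            for role, (kind, ref) in ed.args:
                if kind == "ent":
                    args.append((role, doc.entities[ent_lookup[ref]]))
                else:
                    args.append((role, local_events[ref]))
            ev = EventAnn(id=eid, event_type=ed.event_type, trigger=trig,
                          args=args)
            local_events.append(ev)
            doc.events[eid] = ev
    return doc


def generate_corpus(cfg: SynthConfig) -> list[AnnotatedDocument]:
    """Deterministic corpus of annotated documents; ``cfg.seed`` fixes all
    randomness (identical serializations on rerun)."""
    docs: list[AnnotatedDocument] = []
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_docs)
    for di in range(cfg.n_docs):
        rng = np.random.default_rng(seeds[di])
        drafts = [_build_sentence(cfg, rng)
                  for _ in range(cfg.sentences_per_doc)]
        doc = _assemble_document(f"SYN{di:04d}", drafts)
        if cfg.p_insert or cfg.p_relabel or cfg.p_flip:
            doc = replace_graphs(doc, [
                perturb(g, cfg.p_insert, cfg.p_relabel, cfg.p_flip,
                        rng=rng, relabel_pool=cfg.relabel_pool)
                for g in doc.sentences])
        docs.append(doc)
    return docs


def replace_graphs(doc: AnnotatedDocument,
                   graphs: list[DepGraph]) -> AnnotatedDocument:
    """Same annotations over substituted sentence graphs."""
    return AnnotatedDocument(doc_id=doc.doc_id, text=doc.text,
                             sentences=graphs, entities=doc.entities,
                             triggers=doc.triggers, events=doc.events)


# -- perturbation -----------------------------------------------------------

def perturb(g: DepGraph, p_insert: float = 0.0, p_relabel: float = 0.0,
            p_flip: float = 0.0, seed: Optional[int] = None,
            rng: Optional[np.random.Generator] = None,
            relabel_pool: Sequence[str] = ("prep_in", "prep_on", "amod"),
            ) -> DepGraph:
    """Structurally perturb a sentence graph, leaving annotations valid.

    Per edge, at most one operation applies: *insert* splices a fresh node
    into the edge (the path between the original endpoints lengthens by
    exactly one), *relabel* replaces the relation label, *flip* reverses
    the direction.  All token indices of the input survive.
    """
    if p_insert + p_relabel + p_flip > 1.0:
        raise ConfigurationError("perturbation rates sum above 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = DepGraph(sentence_id=g.sentence_id)
    for i in g.node_indices():
        t = g.token(i)
        out.add_token(Token(index=i, surface=t.surface, lemma=t.lemma,
                            pos=t.pos, is_entity=t.is_entity,
                            entity_ref=t.entity_ref, is_trigger=t.is_trigger,
                            start=t.start, end=t.end))
    next_idx = max(g.node_indices(), default=0) + 1
    for e in g.edges:
        u = rng.random()
        if u < p_insert:
            out.add_token(Token(index=next_idx, surface="filler",
                                lemma="filler", pos="NN"))
            out.add_edge(DepEdge(governor=e.governor, dependent=next_idx,
                                 label=e.label))
            out.add_edge(DepEdge(governor=next_idx, dependent=e.dependent,
                                 label="dep"))
            next_idx += 1
        elif u < p_insert + p_relabel:
            pool = [l for l in relabel_pool if l != e.label]
            out.add_edge(DepEdge(governor=e.governor, dependent=e.dependent,
                                 label=str(_pick(rng, pool))))
        elif u < p_insert + p_relabel + p_flip:
            out.add_edge(DepEdge(governor=e.dependent, dependent=e.governor,
                                 label=e.label))
        else:
            out.add_edge(e)
    return out


def perturb_corpus(docs: Iterable[AnnotatedDocument], p_insert: float,
                   p_relabel: float, p_flip: float, seed: int,
                   relabel_pool: Sequence[str] = ("prep_in", "prep_on", "amod"),
                   ) -> list[AnnotatedDocument]:
    """Perturb every sentence graph of a corpus, annotations unchanged."""
    docs = list(docs)
    out = []
    ss = np.random.SeedSequence(seed).spawn(len(docs))
    for doc, s in zip(docs, ss):
        rng = np.random.default_rng(s)
        out.append(replace_graphs(doc, [
            perturb(g, p_insert, p_relabel, p_flip, rng=rng,
                    relabel_pool=relabel_pool) for g in doc.sentences]))
    return out


# -- on-disk serialization --------------------------------------------------

def _sd_lines(g: DepGraph) -> str:
    return "\n".join(
        f"{e.label}({g.token(e.governor).surface}-{e.governor}, "
        f"{g.token(e.dependent).surface}-{e.dependent})"
        for e in g.edges)


def _tok_lines(g: DepGraph) -> str:
    return "\n".join(f"{i}\t{t.surface}\t{t.lemma}\t{t.pos}"
                     for i, t in ((i, g.token(i)) for i in g.node_indices()))


def _conll_lines(g: DepGraph) -> str:
    # CoNLL is single-head: parallel edges beyond the first governor of a
    # token are dropped (lossy; the .sd dialect is the faithful one)
    head: dict[int, tuple[int, str]] = {}
    for e in g.edges:
        head.setdefault(e.dependent, (e.governor, e.label))
    rows = []
    for i in g.node_indices():
        t = g.token(i)
        h, label = head.get(i, (0, "root"))
        rows.append(f"{i}\t{t.surface}\t{t.lemma}\t{t.pos}\t{t.pos}\t_"
                    f"\t{h}\t{label}\t_\t_")
    return "\n".join(rows)


def gold_a2_text(doc: AnnotatedDocument) -> str:
    lines = []
    for tid in sorted(doc.triggers, key=lambda x: int(x[1:])):
        t = doc.triggers[tid]
        lines.append(f"{tid}\t{t.event_type} {t.start} {t.end}\t{t.text}")
    for eid in sorted(doc.events, key=lambda x: int(x[1:])):
        ev = doc.events[eid]
        parts = [f"{ev.event_type}:{ev.trigger.id}"]
        for role, filler in ev.args:
            parts.append(f"{role}:{filler.id}")
        lines.append(f"{eid}\t{' '.join(parts)}")
    return "\n".join(lines) + ("\n" if lines else "")


def a1_text(doc: AnnotatedDocument) -> str:
    lines = []
    for tid in sorted(doc.entities, key=lambda x: int(x[1:])):
        e = doc.entities[tid]
        lines.append(f"{tid}\t{e.type} {e.start} {e.end}\t{e.text}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_corpus(docs: Iterable[AnnotatedDocument], outdir) -> None:
    """Write .txt/.a1/.a2 plus parse files in both supported dialects."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (outdir / f"{doc.doc_id}.txt").write_text(doc.text)
        (outdir / f"{doc.doc_id}.a1").write_text(a1_text(doc))
        (outdir / f"{doc.doc_id}.a2").write_text(gold_a2_text(doc))
        (outdir / f"{doc.doc_id}.sd").write_text(
            "\n\n".join(_sd_lines(g) for g in doc.sentences) + "\n")
        (outdir / f"{doc.doc_id}.tok").write_text(
            "\n\n".join(_tok_lines(g) for g in doc.sentences) + "\n")
        (outdir / f"{doc.doc_id}.conll").write_text(
            "\n\n".join(_conll_lines(g) for g in doc.sentences) + "\n")
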