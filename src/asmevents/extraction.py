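"""Iterative bottom-up event assembly from rule matches, plus scoring.

Extraction proceeds in rounds: simple rules (no sub-event slots) are
matched first; their events then become candidate fillers for the
sub-event slots of complex rules, whose slot nodes are relaxed to accept
*any* token that triggers an already-extracted event.  The process repeats
until no new candidate event appears.

Matches of individual-path rule variants that share the same event trigger
token(s) and event type are grouped into one merged candidate event
(multi-theme ``Binding`` events arise this way); candidates without a
Theme are discarded and exact duplicates collapse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional, Sequence, Union

from .asm import ParamSet, match
from .depgraph import DepGraph, generalize_entities
from .errors import IntegrityError
from .rules import ENTITY, SUB_EVENT, EventRule
from .standoff import AnnotatedDocument, EntityAnn, EventAnn, is_theme_role

logger = logging.getLogger(__name__)

MAX_ROUNDS = 20  # safety net; the fixpoint is reached long before this


@dataclass(frozen=True)
class Event:
    """A predicted event: typed trigger plus role-filled arguments, where a
    filler is an entity id or another (nested) Event."""

    event_type: str
    sentence_index: int
    trigger_tokens: frozenset[int]
    args: tuple[tuple[str, Union[str, "Event"]], ...]
    source_rules: frozenset[str] = frozenset()

    def key(self) -> str:
        """Canonical recursive form: type, trigger tokens, normalized roles
        (Theme2/Theme3 → Theme) and canonical fillers, order-insensitive."""
        arg_keys = sorted(
            f"{_norm_role(r)}={f if isinstance(f, str) else f.key()}"
            for r, f in self.args)
        trig = ",".join(str(t) for t in sorted(self.trigger_tokens))
        return f"{self.event_type}@{trig}({';'.join(arg_keys)})"

    def closure_keys(self) -> set[tuple[str, frozenset[int]]]:
        out = {(self.event_type, self.trigger_tokens)}
        for _, f in self.args:
            if isinstance(f, Event):
                out |= f.closure_keys()
        return out

    def has_theme(self) -> bool:
        return any(is_theme_role(r) for r, _ in self.args)


def _norm_role(role: str) -> str:
    return "Theme" if is_theme_role(role) else role


@dataclass
class PRF:
    """Precision / recall / F-score counts."""

    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


# -- gold conversion --------------------------------------------------------

def gold_event(doc: AnnotatedDocument, ev: EventAnn) -> Event:
    """Token-anchored form of a gold event, comparable with predictions."""
    args = []
    for role, filler in ev.args:
        if isinstance(filler, EntityAnn):
            args.append((role, filler.id))
        else:
            args.append((role, gold_event(doc, filler)))
    return Event(event_type=ev.event_type,
                 sentence_index=ev.sentence_index,
                 trigger_tokens=frozenset(ev.trigger.tokens),
                 args=tuple(args))


# -- sentence-level extraction ----------------------------------------------

@dataclass
class _Anchor:
    """One argument anchor from an individual-variant match."""

    role: str
    token: int
    filler: Union[str, Event]
    rule_id: str


def _slot_fillers(slot_kind: str, token: int,
                  entity_at: dict[int, str],
                  events_at: dict[int, list[Event]],
                  host_key: tuple[str, frozenset[int]]
                  ) -> list[Union[str, Event]]:
    if slot_kind == ENTITY:
        eid = entity_at.get(token)
        return [eid] if eid is not None else []
    options = []
    for ev in events_at.get(token, []):
        if host_key in ev.closure_keys():
            continue  # would nest an event inside itself
        options.append(ev)
    return options


def extract_sentence(sentence: DepGraph,
                     entities: Sequence[tuple[str, int]],
                     ruleset: Sequence[EventRule],
                     params: ParamSet,
                     trigger_lexicon: Optional[frozenset[str]] = None,
                     sentence_index: int = 0) -> list[Event]:
    """Fixpoint of bottom-up rule matching on one sentence.

    ``entities`` are (entity id, head token) pairs; the sentence is
    entity-generalized here before matching.
    """
    gg = generalize_entities(sentence, entities)
    entity_at = {head: eid for eid, head in entities}
    simple = [r for r in ruleset if not r.is_complex]
    complex_rules = [r for r in ruleset if r.is_complex]

    events: dict[str, Event] = {}

    def events_at_tokens() -> dict[int, list[Event]]:
        at: dict[int, list[Event]] = {}
        for ev in events.values():
            for t in ev.trigger_tokens:
                at.setdefault(t, []).append(ev)
        return at

    def add(ev: Event) -> bool:
        if not ev.has_theme():
            return False
        k = ev.key()
        if k in events:
            old = events[k]
            merged = old.source_rules | ev.source_rules
            if merged != old.source_rules:
                events[k] = Event(event_type=old.event_type,
                                  sentence_index=old.sentence_index,
                                  trigger_tokens=old.trigger_tokens,
                                  args=old.args, source_rules=merged)
            return False
        events[k] = ev
        return True

    def candidates_from_matches(rules: Sequence[EventRule],
                                sub_tokens: Optional[frozenset[int]]
                                ) -> tuple[list[Event], list[tuple[str, frozenset[int], _Anchor]]]:
        direct: list[Event] = []
        anchors: list[tuple[str, frozenset[int], _Anchor]] = []
        events_at = events_at_tokens()
        for rule in rules:
            for m in match(rule, gg, params, trigger_lexicon, sub_tokens):
                trig = frozenset(m.mapping[t] for t in rule.trigger_nodes)
                host_key = (rule.event_type, trig)
                slot_opts: list[list[tuple[str, Union[str, Event]]]] = []
                ok = True
                for slot in rule.slots:
                    tok = m.mapping[slot.node]
                    fillers = _slot_fillers(slot.kind, tok, entity_at,
                                            events_at, host_key)
                    if not fillers:
                        ok = False
                        break
                    slot_opts.append([(slot.role, f) for f in fillers])
                if not ok:
                    continue
                if rule.variant == "union":
                    for combo in product(*slot_opts):
                        direct.append(Event(
                            event_type=rule.event_type,
                            sentence_index=sentence_index,
                            trigger_tokens=trig, args=tuple(combo),
                            source_rules=frozenset({rule.rule_id})))
                else:
                    slot = rule.slots[0]
                    for role, filler in slot_opts[0]:
                        anchors.append((rule.event_type, trig, _Anchor(
                            role=role, token=m.mapping[slot.node],
                            filler=filler, rule_id=rule.rule_id)))
        return direct, anchors

    def run_round(rules: Sequence[EventRule],
                  sub_tokens: Optional[frozenset[int]]) -> bool:
        direct, anchors = candidates_from_matches(rules, sub_tokens)
        new = False
        for ev in direct:
            new |= add(ev)
        for ev in group_arguments(anchors, sentence_index):
            new |= add(ev)
        return new

    run_round(simple, None)
    for _ in range(MAX_ROUNDS):
        sub_tokens = frozenset(t for ev in events.values()
                               for t in ev.trigger_tokens)
        if not complex_rules:
            break
        if not run_round(complex_rules, sub_tokens):
            break
    else:
        logger.warning("sentence %s: extraction round cap reached",
                       sentence.sentence_id)
    return sorted(events.values(), key=Event.key)


def group_arguments(anchors: Iterable[tuple[str, frozenset[int], "_Anchor"]],
                    sentence_index: int = 0) -> list[Event]:
    """Merge individual-variant argument anchors that share an event
    trigger into candidate events.

    Within one (event type, trigger) group, anchors are collected per
    (role, anchor token) slot; alternative fillers of the same slot (a
    token triggering several extracted events) fan out into alternative
    candidates.  Groups without any Theme anchor produce nothing.
    """
    groups: dict[tuple[str, frozenset[int]],
                 dict[tuple[str, int], list[_Anchor]]] = {}
    for etype, trig, anchor in anchors:
        slots = groups.setdefault((etype, trig), {})
        key = (_norm_role(anchor.role), anchor.token)
        slots.setdefault(key, []).append(anchor)
    out: list[Event] = []
    for (etype, trig), slots in sorted(groups.items(),
                                       key=lambda kv: (kv[0][0], sorted(kv[0][1]))):
        if not any(is_theme_role(role) for role, _ in slots):
            continue
        slot_keys = sorted(slots)
        filler_choices = []
        rule_ids = frozenset(a.rule_id for anchors_ in slots.values()
                             for a in anchors_)
        for sk in slot_keys:
            uniq: list[Union[str, Event]] = []
            seen: set[str] = set()
            for a in slots[sk]:
                fk = _filler_key(a.filler)
                if fk not in seen:
                    seen.add(fk)
                    uniq.append(a.filler)
            filler_choices.append(uniq)
        for combo in product(*filler_choices):
            args = tuple((sk[0], filler)
                         for sk, filler in zip(slot_keys, combo))
            out.append(Event(event_type=etype, sentence_index=sentence_index,
                             trigger_tokens=trig, args=args,
                             source_rules=rule_ids))
    return out


def _filler_key(f: Union[str, Event]) -> str:
    return f if isinstance(f, str) else f.key()


# -- corpus-level driver ----------------------------------------------------

def extract_corpus(docs: Iterable[AnnotatedDocument],
                   ruleset: Sequence[EventRule],
                   params: ParamSet,
                   trigger_lexicon: Optional[frozenset[str]] = None
                   ) -> dict[str, list[Event]]:
    """Apply ``extract_sentence`` to every sentence of every document;
    deterministic across runs."""
    out: dict[str, list[Event]] = {}
    for doc in docs:
        events: list[Event] = []
        for si, g in enumerate(doc.sentences):
            events.extend(extract_sentence(
                g, doc.sentence_entities(si), ruleset, params,
                trigger_lexicon, sentence_index=si))
        out[doc.doc_id] = events
    return out


# -- scoring ----------------------------------------------------------------

def _approx_trigger(p: frozenset[int], g: frozenset[int]) -> bool:
    return (abs(min(p) - min(g)) <= 1 and abs(max(p) - max(g)) <= 1)


def _approx_match(pred: Event, gold: Event) -> bool:
    if pred.event_type != gold.event_type:
        return False
    if pred.sentence_index != gold.sentence_index:
        return False
    if not _approx_trigger(pred.trigger_tokens, gold.trigger_tokens):
        return False
    if len(pred.args) != len(gold.args):
        return False
    unused = list(gold.args)
    for role, filler in pred.args:
        hit = None
        for i, (grole, gfiller) in enumerate(unused):
            if _norm_role(role) != _norm_role(grole):
                continue
            if isinstance(filler, str) or isinstance(gfiller, str):
                if filler == gfiller:
                    hit = i
                    break
            elif _approx_match(filler, gfiller):
                hit = i
                break
        if hit is None:
            return False
        unused.pop(hit)
    return True


def score(predicted: dict[str, list[Event]],
          gold_docs: Iterable[AnnotatedDocument],
          mode: str = "strict") -> dict[str, PRF]:
    """Score predictions against gold events.

    ``strict``: an event is a true positive iff its type, trigger token set
    and full recursive argument structure match a gold event.
    ``approx_span``: trigger token spans may differ by one token on each
    side (recursively).  Returns one PRF per event type plus ``"overall"``.
    """
    if mode not in ("strict", "approx_span"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    gold_by_doc = {}
    for doc in gold_docs:
        if doc.doc_id in gold_by_doc:
            raise IntegrityError(f"duplicate document id {doc.doc_id}")
        gold_by_doc[doc.doc_id] = [gold_event(doc, ev)
                                   for ev in sorted(doc.events.values(),
                                                    key=lambda e: e.id)]
    table: dict[str, PRF] = {"overall": PRF()}

    def bucket(etype: str) -> PRF:
        return table.setdefault(etype, PRF())

    for doc_id, gold in gold_by_doc.items():
        preds = list(predicted.get(doc_id, []))
        if mode == "strict":
            gold_keys = {g.key() for g in gold}
            pred_keys = {p.key(): p for p in preds}
            for k, p in pred_keys.items():
                if k in gold_keys:
                    bucket(p.event_type).tp += 1
                    table["overall"].tp += 1
                else:
                    bucket(p.event_type).fp += 1
                    table["overall"].fp += 1
            for g in gold:
                if g.key() not in pred_keys:
                    bucket(g.event_type).fn += 1
                    table["overall"].fn += 1
        else:
            matched: set[int] = set()
            seen_keys: set[str] = set()
            uniq_preds = []
            for p in preds:
                if p.key() not in seen_keys:
                    seen_keys.add(p.key())
                    uniq_preds.append(p)
            for g in gold:
                hit = None
                for i, p in enumerate(uniq_preds):
                    if i not in matched and _approx_match(p, g):
                        hit = i
                        break
                if hit is None:
                    bucket(g.event_type).fn += 1
                    table["overall"].fn += 1
                else:
                    matched.add(hit)
                    bucket(g.event_type).tp += 1
                    table["overall"].tp += 1
            for i, p in enumerate(uniq_preds):
                if i not in matched:
                    bucket(p.event_type).fp += 1
                    table["overall"].fp += 1
    return table


def format_prf_table(table: dict[str, PRF]) -> str:
    """Render a per-type PRF table with an overall row."""
    rows = [f"{'Event type':<24}{'Recall(%)':>10}{'Precision(%)':>14}{'F-score(%)':>12}"]
    for etype in sorted(t for t in table if t != "overall"):
        prf = table[etype]
        rows.append(f"{etype:<24}{100 * prf.recall:>10.2f}"
                    f"{100 * prf.precision:>14.2f}{100 * prf.f_score:>12.2f}")
    prf = table["overall"]
    rows.append(f"{'TOTAL':<24}{100 * prf.recall:>10.2f}"
                f"{100 * prf.precision:>14.2f}{100 * prf.f_score:>12.2f}")
    return "\n".join(rows)
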