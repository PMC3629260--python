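"""Rule-set optimization and matching-parameter search.

Instance-based rule sets inherit false-positive behaviour from contexts
that look like events but are not (e.g. a noun-compound rule learned from
"expression of TNF mRNA" firing on "level of TNF mRNA").  Each rule is
therefore evaluated on the training corpus, leaving out the sentence it
was induced from, and rules whose TP:FP ratio falls below a threshold
(default 1:4) are pruned.  Because nested events make complex rules depend
on the sub-events other rules produce, pruning iterates — sentence
matching, rule ranking, rule removal — until the rule set converges.
Silent rules (no predictions at all) are always kept.

Parameter search encodes thresholds and weights as integers in [0, 50] and
maximizes the strict F-score on a development corpus, either exhaustively
(small grids) or with a seeded genetic algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import product
from typing import Optional, Sequence

import numpy as np

from .asm import ParamSet, match
from .errors import ConfigurationError
from .extraction import Event, extract_corpus, extract_sentence, gold_event, score
from .rules import SUB_EVENT, EventRule
from .standoff import AnnotatedDocument

logger = logging.getLogger(__name__)


@dataclass
class RuleStats:
    """Leave-origin-out prediction counts of one rule."""

    rule_id: str
    tp: int = 0
    fp: int = 0

    @property
    def made_prediction(self) -> bool:
        return (self.tp + self.fp) > 0

    @property
    def ratio(self) -> float:
        if self.fp == 0:
            return float("inf")
        return self.tp / self.fp


def _provenance_pairs(rule: EventRule) -> set[tuple[str, str]]:
    return {(doc_id, sent_id) for doc_id, sent_id, _ in rule.provenance}


def rule_stats(rule: EventRule, docs: Sequence[AnnotatedDocument],
               params: ParamSet,
               trigger_lexicon: Optional[frozenset[str]] = None) -> RuleStats:
    """Predictions of this rule alone over all training sentences except
    its origin sentence(s).

    For complex rules, *gold* sub-events stand in as substitutable
    sub-event fillers, isolating the rule's own quality from other rules'
    errors.  A prediction counts as TP when it strictly matches a gold
    event.
    """
    stats = RuleStats(rule_id=rule.rule_id)
    origins = _provenance_pairs(rule)
    for doc in docs:
        for si, g in enumerate(doc.sentences):
            if (doc.doc_id, g.sentence_id) in origins:
                continue
            gold = [gold_event(doc, ev) for ev in doc.sentence_events(si)]
            gold_keys = {e.key() for e in gold}
            preds = extract_sentence(
                g, doc.sentence_entities(si), [rule], params,
                trigger_lexicon, sentence_index=si,
            ) if not rule.is_complex else _complex_rule_predictions(
                rule, doc, si, gold, params, trigger_lexicon)
            for p in preds:
                if p.key() in gold_keys:
                    stats.tp += 1
                else:
                    stats.fp += 1
    return stats


def _complex_rule_predictions(rule: EventRule, doc: AnnotatedDocument,
                              si: int, gold: Sequence[Event],
                              params: ParamSet,
                              trigger_lexicon: Optional[frozenset[str]]
                              ) -> list[Event]:
    """Single complex rule with gold sub-events available as fillers."""
    from .extraction import _Anchor, group_arguments  # shared grouping path

    g = doc.sentences[si]
    entities = doc.sentence_entities(si)
    from .depgraph import generalize_entities
    gg = generalize_entities(g, entities)
    entity_at = {head: eid for eid, head in entities}
    events_at: dict[int, list[Event]] = {}
    for ev in gold:
        for t in ev.trigger_tokens:
            events_at.setdefault(t, []).append(ev)
    sub_tokens = frozenset(events_at)

    out: dict[str, Event] = {}
    anchors = []
    for m in match(rule, gg, params, trigger_lexicon, sub_tokens):
        trig = frozenset(m.mapping[t] for t in rule.trigger_nodes)
        host_key = (rule.event_type, trig)
        slot_opts = []
        ok = True
        for slot in rule.slots:
            tok = m.mapping[slot.node]
            if slot.kind == SUB_EVENT:
                fillers = [ev for ev in events_at.get(tok, [])
                           if host_key not in ev.closure_keys()]
            else:
                fillers = ([entity_at[tok]] if tok in entity_at else [])
            if not fillers:
                ok = False
                break
            slot_opts.append([(slot.role, f) for f in fillers])
        if not ok:
            continue
        if rule.variant == "union":
            for combo in product(*slot_opts):
                ev = Event(event_type=rule.event_type, sentence_index=si,
                           trigger_tokens=trig, args=tuple(combo),
                           source_rules=frozenset({rule.rule_id}))
                if ev.has_theme():
                    out[ev.key()] = ev
        else:
            slot = rule.slots[0]
            for role, filler in slot_opts[0]:
                anchors.append((rule.event_type, trig, _Anchor(
                    role=role, token=m.mapping[slot.node], filler=filler,
                    rule_id=rule.rule_id)))
    for ev in group_arguments(anchors, si):
        out.setdefault(ev.key(), ev)
    return list(out.values())


def pipeline_rule_stats(ruleset: Sequence[EventRule],
                        docs: Sequence[AnnotatedDocument],
                        params: ParamSet,
                        trigger_lexicon: Optional[frozenset[str]] = None
                        ) -> dict[str, RuleStats]:
    """Per-rule TP/FP from full bottom-up extraction with the current rule
    set (each sentence matched by the rules not induced from it); every
    prediction is credited to all rules that produced it.

    Unlike :func:`rule_stats`, complex rules here consume the sub-events
    the *current* rule set actually predicts, so removing a rule can change
    dependent rules' statistics in the next pruning iteration.
    """
    stats = {r.rule_id: RuleStats(rule_id=r.rule_id) for r in ruleset}
    origins = {r.rule_id: _provenance_pairs(r) for r in ruleset}
    for doc in docs:
        for si, g in enumerate(doc.sentences):
            key = (doc.doc_id, g.sentence_id)
            active = [r for r in ruleset if key not in origins[r.rule_id]]
            if not active:
                continue
            gold_keys = {gold_event(doc, ev).key()
                         for ev in doc.sentence_events(si)}
            preds = extract_sentence(g, doc.sentence_entities(si), active,
                                     params, trigger_lexicon,
                                     sentence_index=si)
            for p in preds:
                good = p.key() in gold_keys
                for rid in p.source_rules:
                    if good:
                        stats[rid].tp += 1
                    else:
                        stats[rid].fp += 1
    return stats


def optimize_ruleset(ruleset: Sequence[EventRule],
                     docs: Sequence[AnnotatedDocument],
                     params: ParamSet,
                     trigger_lexicon: Optional[frozenset[str]] = None,
                     history: Optional[list[set[str]]] = None
                     ) -> list[EventRule]:
    """Iteratively prune predicting rules whose leave-origin-out TP:FP
    ratio is below ``params.rho`` until the rule set converges.

    Silent rules are never removed; the result is a subset of the input.
    Convergence takes at most ``len(ruleset)`` iterations since every
    non-final iteration removes at least one rule.  When ``history`` is
    given, the set of rule ids removed by each iteration is appended to it.
    """
    active = list(ruleset)
    for iteration in range(1, len(ruleset) + 2):
        stats = pipeline_rule_stats(active, docs, params, trigger_lexicon)
        doomed = {rid for rid, s in stats.items()
                  if s.made_prediction and s.ratio < params.rho}
        if not doomed:
            logger.info("rule-set optimization converged after %d "
                        "iteration(s); %d/%d rules kept",
                        iteration, len(active), len(ruleset))
            break
        logger.info("iteration %d: removing %d rule(s)", iteration,
                    len(doomed))
        if history is not None:
            history.append(doomed)
        active = [r for r in active if r.rule_id not in doomed]
    return active


# -- parameter search -------------------------------------------------------

@dataclass
class SearchConfig:
    """Budget and encoding of the integer parameter search."""

    generations: int = 50
    population: int = 100
    low: int = 0
    high: int = 50
    seed: int = 0
    tune_weights: bool = True
    tournament_k: int = 2
    crossover_p: float = 0.5
    mutation_p: float = 0.1
    elitism: int = 1

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ConfigurationError("population must be >= 2")
        if self.low > self.high:
            raise ConfigurationError("integer range low > high")


def _params_from_genes(genes: Sequence[int], types: Sequence[str],
                       base: ParamSet, tune_weights: bool) -> ParamSet:
    eta = {t: float(v) for t, v in zip(types, genes)}
    if tune_weights:
        w_s, w_l, w_d = (float(v) for v in genes[len(types):])
    else:
        w_s, w_l, w_d = base.weights
    return replace(base, eta=eta, w_s=w_s, w_l=w_l, w_d=w_d)


def _fitness(genes: Sequence[int], types: Sequence[str], base: ParamSet,
             tune_weights: bool, rules: Sequence[EventRule],
             dev_docs: Sequence[AnnotatedDocument],
             trigger_lexicon: Optional[frozenset[str]]) -> float:
    p = _params_from_genes(genes, types, base, tune_weights)
    preds = extract_corpus(dev_docs, rules, p, trigger_lexicon)
    return score(preds, dev_docs, mode="strict")["overall"].f_score


def tune(rules: Sequence[EventRule],
         dev_docs: Sequence[AnnotatedDocument],
         search: SearchConfig,
         base_params: Optional[ParamSet] = None,
         trigger_lexicon: Optional[frozenset[str]] = None,
         method: str = "ga") -> ParamSet:
    """Search integer thresholds (one per event type in the rule set) and,
    optionally, the three distance weights, maximizing strict F on the
    development corpus.  Seeded and reproducible; ties prefer the smallest
    thresholds, then the smallest weights (the most conservative matcher).

    ``method="grid"`` runs the exhaustive fallback (practical only for
    small parameter spaces, e.g. one free threshold).
    """
    if not dev_docs:
        raise ConfigurationError("development corpus is empty")
    base = base_params or ParamSet()
    types = sorted({r.event_type for r in rules})
    n_genes = len(types) + (3 if search.tune_weights else 0)
    if n_genes == 0:
        raise ConfigurationError("nothing to tune: no rules given")

    def better(cand: tuple[float, tuple[int, ...]],
               best: Optional[tuple[float, tuple[int, ...]]]) -> bool:
        if best is None:
            return True
        if cand[0] != best[0]:
            return cand[0] > best[0]
        return cand[1] < best[1]

    best: Optional[tuple[float, tuple[int, ...]]] = None

    def consider(genes: tuple[int, ...]) -> float:
        nonlocal best
        f = _fitness(genes, types, base, search.tune_weights, rules,
                     dev_docs, trigger_lexicon)
        if better((f, genes), best):
            best = (f, genes)
        return f

    if method == "grid":
        values = range(search.low, search.high + 1)
        for genes in product(values, repeat=n_genes):
            consider(genes)
    elif method == "ga":
        rng = np.random.default_rng(search.seed)
        pop = rng.integers(search.low, search.high + 1,
                           size=(search.population, n_genes))
        fit = np.array([consider(tuple(int(v) for v in ind)) for ind in pop])
        for _ in range(search.generations):
            order = np.argsort(-fit, kind="stable")
            nxt = [pop[order[i]].copy() for i in range(search.elitism)]
            while len(nxt) < search.population:
                idx = rng.integers(0, search.population, size=search.tournament_k)
                a = idx[np.argmax(fit[idx])]
                idx = rng.integers(0, search.population, size=search.tournament_k)
                b = idx[np.argmax(fit[idx])]
                mask = rng.random(n_genes) < search.crossover_p
                child = np.where(mask, pop[a], pop[b])
                mut = rng.random(n_genes) < search.mutation_p
                child[mut] = rng.integers(search.low, search.high + 1,
                                          size=int(mut.sum()))
                nxt.append(child)
            pop = np.array(nxt)
            fit = np.array([consider(tuple(int(v) for v in ind))
                            for ind in pop])
    else:
        raise ConfigurationError(f"unknown search method {method!r}")

    assert best is not None
    return _params_from_genes(best[1], types, base, search.tune_weights)
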