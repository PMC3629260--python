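"""Approximate subgraph matching (ASM) of rule graphs against sentences.

A rule graph ``G_r`` matches a sentence graph ``G_s`` when an injective
node mapping ``f : V_r → V_s`` exists whose *subgraph distance*

    subgraphDist = w_s·structDist + w_l·labelDist + w_d·directionalityDist

falls within a per-event-type threshold η (inclusive; η = 0 demands exact
agreement).  The three penalty components compare, over every unordered
pair of rule nodes, the shortest undirected dependency path inside the rule
graph with the shortest path between the mapped nodes in the sentence:

* ``structDist`` accumulates absolute differences of path lengths,
  normalized by the sum of rule-side path lengths;
* ``labelDist`` counts edge-label disagreements (multiset symmetric
  difference, so ``prep_of`` vs ``prep_in`` costs 2), normalized by the
  total number of labels on both paths;
* ``directionalityDist`` does the same for edge orientations relative to a
  fixed traversal of each path.

Node pairs are admitted by configurable matching criteria over POS tags
(``P`` exact, ``P*`` relaxed word-class), lemmas (``L``), exact tokens
(``A``) and a known-trigger lexicon (``T``); masked ``BIO_Entity`` rule
nodes match exactly the entity-flagged sentence tokens.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Callable, Iterable, Optional

from .depgraph import DepGraph, Path, Token
from .errors import ConfigurationError
from .rules import EventRule

logger = logging.getLogger(__name__)

#: Relaxed POS classes: plural/singular nouns collapse, verb conjugations
#: collapse, comparative/superlative adjectives and adverbs collapse.
_POS_CLASSES = [
    {"NN", "NNS"},
    {"NNP", "NNPS"},
    {"VB", "VBD", "VBG", "VBN", "VBP", "VBZ"},
    {"JJ", "JJR", "JJS"},
    {"RB", "RBR", "RBS"},
]
_POS_CLASS_OF = {pos: f"class{i}" for i, cls in enumerate(_POS_CLASSES)
                 for pos in cls}

VALID_FEATURES = frozenset({"P", "P*", "L", "A", "T"})


def relaxed_pos(pos: str) -> str:
    return _POS_CLASS_OF.get(pos, pos)


@dataclass(frozen=True)
class MatchCriteria:
    """Conjunction of node features two tokens must share to be matchable."""

    features: frozenset[str]

    def __post_init__(self) -> None:
        if not self.features:
            raise ConfigurationError("matching criteria must be non-empty")
        unknown = self.features - VALID_FEATURES
        if unknown:
            raise ConfigurationError(f"unknown matching features {unknown}")

    @classmethod
    def parse(cls, text: str) -> "MatchCriteria":
        return cls(frozenset(f.strip() for f in text.split("+") if f.strip()))

    def __str__(self) -> str:
        order = ["P", "P*", "T", "L", "A"]
        return "+".join(f for f in order if f in self.features)


DEFAULT_CRITERIA = MatchCriteria.parse("P*+L")

#: Per-event-type distance thresholds and component weights tuned for the
#: GENIA event extraction task (integer search in [0, 50]).
GE_THRESHOLDS = {
    "Gene_expression": 7,
    "Transcription": 5,
    "Protein_catabolism": 7,
    "Phosphorylation": 10,
    "Localization": 10,
    "Binding": 7,
    "Regulation": 3,
    "Positive_regulation": 3,
    "Negative_regulation": 3,
}
GE_WEIGHTS = (10.0, 10.0, 10.0)


@dataclass
class ParamSet:
    """Matching parameters: component weights, per-type thresholds,
    node-match criteria, pruning ratio, enumeration guard."""

    w_s: float = 10.0
    w_l: float = 10.0
    w_d: float = 10.0
    eta: dict[str, float] = field(default_factory=dict)
    default_eta: float = 0.0
    criteria: MatchCriteria = DEFAULT_CRITERIA
    rho: float = 0.25
    scheme_cap: int = 100_000

    def __post_init__(self) -> None:
        if min(self.w_s, self.w_l, self.w_d) < 0:
            raise ConfigurationError("distance weights must be non-negative")
        if self.default_eta < 0 or any(v < 0 for v in self.eta.values()):
            raise ConfigurationError("thresholds must be non-negative")
        if self.scheme_cap < 1:
            raise ConfigurationError("scheme_cap must be positive")

    def threshold(self, event_type: str) -> float:
        return self.eta.get(event_type, self.default_eta)

    def with_uniform_eta(self, value: float) -> "ParamSet":
        return replace(self, eta={}, default_eta=value)

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.w_s, self.w_l, self.w_d)


def ge_default_params() -> ParamSet:
    """The shipped GENIA-task profile: Table-style thresholds, equal
    weights 10, criteria P*+L, pruning ratio 1:4."""
    return ParamSet(w_s=GE_WEIGHTS[0], w_l=GE_WEIGHTS[1], w_d=GE_WEIGHTS[2],
                    eta=dict(GE_THRESHOLDS))


@dataclass
class MatchResult:
    """One accepted injective mapping with its distance components."""

    rule: EventRule
    mapping: dict[int, int]  # rule node -> sentence node
    struct_d: float
    label_d: float
    dir_d: float
    total: float

    @property
    def rule_id(self) -> str:
        return self.rule.rule_id

    def mapping_key(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(self.mapping.items()))


# -- node matching ----------------------------------------------------------

def match_node(rule_token: Token, sent_token: Token,
               criteria: MatchCriteria,
               trigger_lexicon: Optional[frozenset[str]] = None) -> bool:
    """Can a rule node match a sentence token under the given criteria?

    ``BIO_Entity`` rule nodes match exactly the entity-flagged sentence
    tokens, with all lexical feature checks skipped; a non-entity rule node
    never matches a masked entity token.
    """
    if rule_token.is_entity or sent_token.is_entity:
        return rule_token.is_entity and sent_token.is_entity
    f = criteria.features
    if "P" in f and rule_token.pos != sent_token.pos:
        return False
    if "P*" in f and relaxed_pos(rule_token.pos) != relaxed_pos(sent_token.pos):
        return False
    if "L" in f:
        if not rule_token.lemma or not sent_token.lemma:
            raise ConfigurationError(
                "lemma-based matching (L) requires lemmas on both tokens; "
                f"missing on {rule_token.surface!r} or {sent_token.surface!r}")
        if rule_token.lemma.lower() != sent_token.lemma.lower():
            return False
    if "A" in f and rule_token.surface != sent_token.surface:
        return False
    if "T" in f and rule_token.is_trigger:
        if trigger_lexicon is None:
            raise ConfigurationError(
                "criterion T requires a trigger lexicon")
        if (sent_token.lemma or sent_token.surface).lower() not in trigger_lexicon:
            return False
    return True


NodeMatcher = Callable[[int, Token], bool]


def make_node_matcher(rule: EventRule, criteria: MatchCriteria,
                      trigger_lexicon: Optional[frozenset[str]] = None,
                      sub_event_tokens: Optional[frozenset[int]] = None,
                      relax_sub_events: bool = True) -> NodeMatcher:
    """Node predicate for one rule.

    Sub-event slot nodes are relaxed: any sentence token that triggers an
    already-extracted event can fill them, with lexical features ignored
    (``relax_sub_events=False`` restores the strict lexical reading).
    """
    sub_nodes = rule.sub_event_nodes if relax_sub_events else frozenset()

    def matcher(rule_node: int, sent_token: Token) -> bool:
        if rule_node in sub_nodes:
            return sent_token.index in (sub_event_tokens or frozenset())
        return match_node(rule.graph.token(rule_node), sent_token,
                          criteria, trigger_lexicon)

    return matcher


# -- start nodes ------------------------------------------------------------

def start_node(rule: EventRule) -> int:
    """The rule's single start node: the lowest-numbered ``BIO_Entity``
    token if any exists, else the lowest-numbered token."""
    entities = rule.graph.entity_indices()
    if entities:
        return entities[0]
    return min(rule.graph.tokens)


def candidate_start_nodes(sentence: DepGraph, rule: EventRule) -> list[int]:
    """Sentence tokens that may pair with the rule's start node: every
    entity token when the rule starts at an entity, else every token."""
    if rule.graph.token(start_node(rule)).is_entity:
        return sentence.entity_indices()
    return sentence.node_indices()


# -- candidate mapping enumeration ------------------------------------------

def enumerate_mappings(rule: EventRule, sentence: DepGraph,
                       criteria: MatchCriteria,
                       start_pair: tuple[int, int],
                       scheme_cap: int = 100_000,
                       node_matcher: Optional[NodeMatcher] = None
                       ) -> list[dict[int, int]]:
    """All complete injective rule→sentence node mappings extending
    ``start_pair``, in deterministic (ascending) order.

    Exceeding ``scheme_cap`` candidate schemes aborts this start pair with
    a logged warning (the documented worst case is exponential).
    """
    if node_matcher is None:
        node_matcher = make_node_matcher(rule, criteria)
    r_start, s_start = start_pair
    remaining = [n for n in sorted(rule.graph.tokens) if n != r_start]
    candidates: dict[int, list[int]] = {}
    for rn in remaining:
        cands = [sn for sn in sentence.node_indices()
                 if sn != s_start and node_matcher(rn, sentence.token(sn))]
        if not cands:
            return []
        candidates[rn] = cands

    out: list[dict[int, int]] = []
    used = {s_start}
    assignment = {r_start: s_start}

    def extend(i: int) -> bool:
        if i == len(remaining):
            if len(out) >= scheme_cap:
                return False
            out.append(dict(assignment))
            return True
        rn = remaining[i]
        for sn in candidates[rn]:
            if sn in used:
                continue
            used.add(sn)
            assignment[rn] = sn
            ok = extend(i + 1)
            used.discard(sn)
            del assignment[rn]
            if not ok:
                return False
        return True

    if not extend(0):
        logger.warning(
            "scheme cap %d exceeded for rule %s at start pair %s; "
            "start pair aborted", scheme_cap, rule.rule_id, start_pair)
        return []
    return out


# -- distance components ----------------------------------------------------

def _rule_pairs(rule: EventRule):
    return combinations(sorted(rule.graph.tokens), 2)


def struct_dist(rule: EventRule, sentence: DepGraph,
                mapping: dict[int, int]) -> float:
    """Normalized accumulated |rule path length − sentence path length|
    over all unordered pairs of rule nodes; ``inf`` when a mapped pair is
    disconnected in the sentence (the candidate is rejected)."""
    num = 0.0
    den = 0.0
    for u, v in _rule_pairs(rule):
        d_r = rule.graph.shortest_path_length(u, v)
        d_s = sentence.shortest_path_length(mapping[u], mapping[v])
        if d_s is None:
            return math.inf
        num += abs(d_r - d_s)
        den += d_r
    return num / den if den else 0.0


def _label_counts(path: Path) -> dict[str, int]:
    counts: dict[str, int] = {}
    for e in path.edges:
        counts[e.label] = counts.get(e.label, 0) + 1
    return counts


def _direction_counts(path: Path) -> dict[str, int]:
    counts = {"forward": 0, "backward": 0}
    for i, e in enumerate(path.edges):
        if e.governor == path.nodes[i] and e.dependent == path.nodes[i + 1]:
            counts["forward"] += 1
        else:
            counts["backward"] += 1
    return counts


def _multiset_diff(a: dict, b: dict) -> int:
    keys = set(a) | set(b)
    return sum(abs(a.get(k, 0) - b.get(k, 0)) for k in keys)


def _pair_paths(rule: EventRule, sentence: DepGraph, mapping: dict[int, int]):
    """Select one (rule path, sentence path) per unordered rule-node pair.

    Both graphs may hold several shortest paths for a pair (parallel
    edges); the selected combination minimizes label + orientation
    disagreement, ties broken by lexicographically smallest node sequences
    — the most favorable deterministic reading.  Yields ``None`` for a pair
    disconnected in the sentence.
    """
    for u, v in _rule_pairs(rule):
        rps = rule.graph.all_shortest_paths(u, v)
        sps = sentence.all_shortest_paths(mapping[u], mapping[v])
        if not sps:
            yield None
            return
        best = None
        for rp in rps:
            rl, rd = _label_counts(rp), _direction_counts(rp)
            for sp in sps:
                diff = (_multiset_diff(rl, _label_counts(sp))
                        + _multiset_diff(rd, _direction_counts(sp)))
                key = (diff, rp.sort_key(), sp.sort_key())
                if best is None or key < best[0]:
                    best = (key, rp, sp)
        yield best[1], best[2]


def _label_dir_dists(rule: EventRule, sentence: DepGraph,
                     mapping: dict[int, int]) -> tuple[float, float]:
    lab_num = lab_den = dir_num = dir_den = 0.0
    for sel in _pair_paths(rule, sentence, mapping):
        if sel is None:
            return math.inf, math.inf
        rp, sp = sel
        lab_num += _multiset_diff(_label_counts(rp), _label_counts(sp))
        lab_den += len(rp) + len(sp)
        dir_num += _multiset_diff(_direction_counts(rp), _direction_counts(sp))
        dir_den += len(rp) + len(sp)
    return (lab_num / lab_den if lab_den else 0.0,
            dir_num / dir_den if dir_den else 0.0)


def label_dist(rule: EventRule, sentence: DepGraph,
               mapping: dict[int, int]) -> float:
    """Edge-label disagreement in [0, 1] (multiset symmetric difference per
    pair, normalized by the total label count on both paths)."""
    return _label_dir_dists(rule, sentence, mapping)[0]


def directionality_dist(rule: EventRule, sentence: DepGraph,
                        mapping: dict[int, int]) -> float:
    """Edge-orientation disagreement in [0, 1], orientation taken relative
    to the traversal from the lower-indexed endpoint of each pair."""
    return _label_dir_dists(rule, sentence, mapping)[1]


def subgraph_distance(struct_d: float, label_d: float, dir_d: float,
                      params: ParamSet) -> float:
    """Weighted sum of the three penalty components."""
    if min(params.w_s, params.w_l, params.w_d) < 0:
        raise ConfigurationError("distance weights must be non-negative")
    return params.w_s * struct_d + params.w_l * label_d + params.w_d * dir_d


# -- main matching ----------------------------------------------------------

def match(rule: EventRule, sentence: DepGraph, params: ParamSet,
          trigger_lexicon: Optional[frozenset[str]] = None,
          sub_event_tokens: Optional[frozenset[int]] = None,
          eta: Optional[float] = None) -> list[MatchResult]:
    """All injective mappings of ``rule`` into ``sentence`` whose subgraph
    distance is within the rule's event-type threshold (inclusive)."""
    if eta is None:
        eta = params.threshold(rule.event_type)
    matcher = make_node_matcher(rule, params.criteria, trigger_lexicon,
                                sub_event_tokens)
    r_start = start_node(rule)
    results: list[MatchResult] = []
    seen: set[tuple] = set()
    for s_start in candidate_start_nodes(sentence, rule):
        if not matcher(r_start, sentence.token(s_start)):
            continue
        for mapping in enumerate_mappings(rule, sentence, params.criteria,
                                          (r_start, s_start),
                                          scheme_cap=params.scheme_cap,
                                          node_matcher=matcher):
            key = tuple(sorted(mapping.items()))
            if key in seen:
                continue
            seen.add(key)
            s_d = struct_dist(rule, sentence, mapping)
            if math.isinf(s_d) or params.w_s * s_d > eta:
                continue
            l_d, d_d = _label_dir_dists(rule, sentence, mapping)
            total = subgraph_distance(s_d, l_d, d_d, params)
            if total <= eta:
                results.append(MatchResult(rule=rule, mapping=mapping,
                                           struct_d=s_d, label_d=l_d,
                                           dir_d=d_d, total=total))
    results.sort(key=MatchResult.mapping_key)
    return results
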