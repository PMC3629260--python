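"""Approximate subgraph matching: node criteria, mapping enumeration,
distance components, thresholded matching and its oracle properties."""

import math

import numpy as np
import pytest

from asmevents.asm import (MatchCriteria, ParamSet, candidate_start_nodes,
                           directionality_dist, enumerate_mappings,
                           ge_default_params, label_dist, match, match_node,
                           start_node, struct_dist, subgraph_distance)
from asmevents.depgraph import DepEdge, DepGraph, Token
from asmevents.errors import ConfigurationError
from asmevents.rules import ArgSpec, ENTITY, EventRule, rules_for_event

from helpers import (brute_force_exact_matches, brute_force_mappings,
                     random_instance)

PSL = MatchCriteria.parse("P*+L")


def mk_token(surface, pos, lemma=None, entity=False):
    return Token(1, surface, lemma if lemma is not None else surface.lower(),
                 pos, is_entity=entity)


def simple_rule(tokens, edges, event_type="X"):
    g = DepGraph()
    for t in tokens:
        g.add_token(t)
    for e in edges:
        g.add_edge(e)
    return EventRule(rule_id="r", event_type=event_type, graph=g,
                     trigger_nodes=frozenset({min(g.tokens)}), slots=(),
                     variant="individual")


class TestMatchNode:
    def test_plural_noun_matches_singular_under_relaxed_pos(self):
        rule = mk_token("ligation", "NN")
        sent = mk_token("ligations", "NNS", lemma="ligation")
        assert match_node(rule, sent, PSL)

    def test_verb_conjugations_match_each_other(self):
        assert match_node(mk_token("induces", "VBZ", "induce"),
                          mk_token("induced", "VBD", "induce"), PSL)

    def test_noun_never_matches_verb_class(self):
        assert not match_node(mk_token("lead", "VBP"),
                              mk_token("lead", "NN"), PSL)

    def test_entity_rule_node_matches_only_entity_tokens(self):
        ent_rule = mk_token("PROT1", "NN", entity=True)
        assert not match_node(ent_rule, mk_token("PROT1", "NN"), PSL)
        assert match_node(ent_rule, mk_token("XYZ", "NN", entity=True), PSL)
        assert not match_node(mk_token("PROT1", "NN"),
                              mk_token("PROT1", "NN", entity=True), PSL)

    def test_exact_token_criterion(self):
        a = MatchCriteria.parse("A")
        assert not match_node(mk_token("Expression", "NN", "expression"),
                              mk_token("expression", "NN", "expression"), a)

    def test_missing_lemma_under_l_is_configuration_error(self):
        t1 = Token(1, "word", "", "NN")
        with pytest.raises(ConfigurationError):
            match_node(t1, mk_token("word", "NN"), PSL)

    def test_trigger_criterion_uses_lexicon(self):
        crit = MatchCriteria.parse("P*+L+T")
        rule = mk_token("expression", "NN")
        rule.is_trigger = True
        sent = mk_token("expression", "NN")
        assert match_node(rule, sent, crit,
                          trigger_lexicon=frozenset({"expression"}))
        assert not match_node(rule, sent, crit,
                              trigger_lexicon=frozenset({"binding"}))
        with pytest.raises(ConfigurationError):
            match_node(rule, sent, crit)


class TestStartNodes:
    def test_lowest_entity_node_wins(self):
        rule = simple_rule([Token(4, "a", "a", "NN", is_entity=True),
                            Token(9, "b", "b", "NN", is_entity=True)],
                           [DepEdge(4, 9, "dep")])
        assert start_node(rule) == 4

    def test_lowest_token_when_no_entity(self, reg_example_graph):
        rules = rules_for_event(reg_example_graph, "Positive_regulation",
                                [20], [ArgSpec("Theme", 23, "sub_event")])
        assert start_node(rules[0]) == 20

    def test_single_node_rule(self):
        rule = simple_rule([Token(3, "w", "w", "NN")], [])
        assert start_node(rule) == 3

    def test_entity_start_restricts_candidates_to_sentence_entities(self):
        rule = simple_rule([Token(1, "P", "p", "NN", is_entity=True),
                            Token(2, "binds", "bind", "VBZ")],
                           [DepEdge(2, 1, "nsubj")])
        sent = DepGraph()
        for i, ent in [(1, True), (2, False), (3, True), (4, False)]:
            sent.add_token(Token(i, f"w{i}", f"w{i}", "NN", is_entity=ent))
        assert candidate_start_nodes(sent, rule) == [1, 3]

    def test_no_entities_in_sentence_gives_no_candidates(self):
        rule = simple_rule([Token(1, "P", "p", "NN", is_entity=True)], [])
        sent = DepGraph()
        sent.add_token(Token(1, "w", "w", "NN"))
        assert candidate_start_nodes(sent, rule) == []

    def test_non_entity_rule_considers_every_token(self, chain_graph):
        rule = simple_rule([Token(1, "binding", "binding", "NN")], [])
        assert candidate_start_nodes(chain_graph, rule) == [1, 2, 3]


class TestEnumerateMappings:
    def _sent(self, words):
        g = DepGraph()
        for i, (s, p) in enumerate(words, start=1):
            g.add_token(Token(i, s, s.lower(), p))
        return g

    def test_disjoint_candidate_sets_multiply(self):
        rule = simple_rule([Token(1, "a", "a", "NN"),
                            Token(2, "b", "b", "VBZ")], [DepEdge(1, 2, "x")])
        sent = self._sent([("a", "NN"), ("b", "VBZ"), ("b", "VBZ")])
        maps = enumerate_mappings(rule, sent, PSL, (1, 1))
        assert len(maps) == 2

    def test_injectivity_blocks_shared_sole_candidate(self):
        rule = simple_rule([Token(1, "a", "a", "NN"),
                            Token(2, "a", "a", "NN")], [DepEdge(1, 2, "x")])
        sent = self._sent([("a", "NN"), ("b", "VBZ")])
        assert enumerate_mappings(rule, sent, PSL, (1, 1)) == []

    def test_scheme_cap_aborts_start_pair(self, caplog):
        rule = simple_rule([Token(i, "a", "a", "NN") for i in range(1, 5)],
                           [DepEdge(i, i + 1, "x") for i in range(1, 4)])
        sent = self._sent([("a", "NN")] * 10)
        with caplog.at_level("WARNING"):
            maps = enumerate_mappings(rule, sent, PSL, (1, 1), scheme_cap=5)
        assert maps == []
        assert any("scheme cap" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(40))
    def test_equals_brute_force_injective_assignment(self, seed):
        """The recursive enumeration, unioned over start pairs, returns
        exactly the brute-force injective feature-compatible assignments."""
        rng = np.random.default_rng(seed)
        rule, sent = random_instance(rng, max_rule=5, max_sentence=15)
        r_start = start_node(rule)
        got = []
        from asmevents.asm import make_node_matcher
        matcher = make_node_matcher(rule, PSL)
        for s in candidate_start_nodes(sent, rule):
            if matcher(r_start, sent.token(s)):
                got.extend(enumerate_mappings(rule, sent, PSL, (r_start, s)))
        want = brute_force_mappings(rule, sent, PSL)
        key = lambda m: tuple(sorted(m.items()))
        assert sorted(map(key, got)) == sorted(map(key, want))


class TestDistances:
    def _pair(self):
        """Single-edge rule over a 4-token chain sentence."""
        rule = simple_rule([Token(1, "a", "a", "NN"),
                            Token(2, "b", "b", "NN")],
                           [DepEdge(1, 2, "prep_of")])
        sent = DepGraph()
        for i, s in enumerate(["a", "x", "y", "b"], start=1):
            sent.add_token(Token(i, s, s, "NN"))
        sent.add_edge(DepEdge(1, 2, "prep_of"))
        sent.add_edge(DepEdge(2, 3, "nn"))
        sent.add_edge(DepEdge(3, 4, "dobj"))
        return rule, sent

    def test_distance_preserving_mapping_has_zero_struct(self):
        rule, sent = self._pair()
        assert struct_dist(rule, sent, {1: 1, 2: 2}) == 0.0

    def test_stretched_edge_struct_dist(self):
        # rule edge (length 1) mapped to nodes at sentence distance 3
        rule, sent = self._pair()
        assert struct_dist(rule, sent, {1: 1, 2: 4}) == pytest.approx(2.0)

    def test_disconnected_pair_is_rejected_with_infinity(self):
        rule, _ = self._pair()
        sent = DepGraph()
        sent.add_token(Token(1, "a", "a", "NN"))
        sent.add_token(Token(2, "b", "b", "NN"))
        assert math.isinf(struct_dist(rule, sent, {1: 1, 2: 2}))

    def test_single_node_rule_zero_distances(self):
        rule = simple_rule([Token(1, "a", "a", "NN")], [])
        sent = DepGraph()
        sent.add_token(Token(1, "a", "a", "NN"))
        m = {1: 1}
        assert struct_dist(rule, sent, m) == 0.0
        assert label_dist(rule, sent, m) == 0.0
        assert directionality_dist(rule, sent, m) == 0.0

    def test_prep_of_vs_prep_in_records_two_label_difference(self):
        """One relation label swapped on a length-1 path counts as two
        differing labels, normalizing to 1."""
        rule = simple_rule([Token(1, "increase", "increase", "NN"),
                            Token(2, "immunoreactivity", "immunoreactivity",
                                  "NN")],
                           [DepEdge(1, 2, "prep_of")])
        sent = DepGraph()
        sent.add_token(Token(1, "increase", "increase", "NN"))
        sent.add_token(Token(2, "immunoreactivity", "immunoreactivity", "NN"))
        sent.add_edge(DepEdge(1, 2, "prep_in"))
        assert label_dist(rule, sent, {1: 1, 2: 2}) == pytest.approx(1.0)
        assert directionality_dist(rule, sent, {1: 1, 2: 2}) == 0.0

    def test_half_overlapping_label_multisets(self):
        rule = simple_rule([Token(1, "a", "a", "NN"), Token(2, "m", "m", "NN"),
                            Token(3, "b", "b", "NN")],
                           [DepEdge(1, 2, "nsubj"), DepEdge(2, 3, "dobj")])
        sent = DepGraph()
        for i, s in enumerate(["a", "m", "b"], start=1):
            sent.add_token(Token(i, s, s, "NN"))
        sent.add_edge(DepEdge(1, 2, "nsubj"))
        sent.add_edge(DepEdge(2, 3, "prep_of"))
        # pair (1,3): {nsubj,dobj} vs {nsubj,prep_of} -> diff 2 of 4
        ld = label_dist(rule, sent, {1: 1, 2: 2, 3: 3})
        # pairs (1,2): 0/2, (1,3): 2/4, (2,3): 2/2 -> total 4/8
        assert ld == pytest.approx(0.5)

    def test_single_flipped_edge_direction(self):
        rule = simple_rule([Token(1, "a", "a", "NN"), Token(2, "b", "b", "NN")],
                           [DepEdge(1, 2, "prep_of")])
        sent = DepGraph()
        sent.add_token(Token(1, "a", "a", "NN"))
        sent.add_token(Token(2, "b", "b", "NN"))
        sent.add_edge(DepEdge(2, 1, "prep_of"))
        assert directionality_dist(rule, sent, {1: 1, 2: 2}) == \
            pytest.approx(1.0)
        assert label_dist(rule, sent, {1: 1, 2: 2}) == 0.0

    def test_mixed_two_edge_path_differs_in_one_slot(self):
        rule = simple_rule([Token(1, "a", "a", "NN"), Token(2, "m", "m", "NN"),
                            Token(3, "b", "b", "NN")],
                           [DepEdge(1, 2, "x"), DepEdge(2, 3, "y")])
        sent = DepGraph()
        for i, s in enumerate(["a", "m", "b"], start=1):
            sent.add_token(Token(i, s, s, "NN"))
        sent.add_edge(DepEdge(1, 2, "x"))
        sent.add_edge(DepEdge(3, 2, "y"))  # second hop reversed
        # pairs: (1,2) 0/2; (1,3) rule {f,f} vs sent {f,b} -> 2/4; (2,3) 2/2
        assert directionality_dist(rule, sent, {1: 1, 2: 2, 3: 3}) == \
            pytest.approx(0.5)

    def test_weighted_total(self):
        p = ParamSet(w_s=10, w_l=10, w_d=10)
        assert subgraph_distance(0.2, 0.5, 0.0, p) == pytest.approx(7.0)
        assert subgraph_distance(0, 0, 0, p) == 0.0
        p2 = ParamSet(w_s=1, w_l=0, w_d=0)
        assert subgraph_distance(0.3, 0.9, 0.9, p2) == pytest.approx(0.3)

    def test_negative_weight_rejected(self):
        with pytest.raises(ConfigurationError):
            ParamSet(w_s=-1)


class TestMatch:
    def test_exact_context_matches_at_zero_threshold(self, reg_example_graph):
        (rule,) = rules_for_event(reg_example_graph, "Positive_regulation",
                                  [20], [ArgSpec("Theme", 23, "sub_event")])
        sent = DepGraph()
        sent.add_token(Token(1, "leads", "lead", "VBZ"))
        sent.add_token(Token(2, "phosphorylation", "phosphorylation", "NN"))
        sent.add_edge(DepEdge(1, 2, "prep_to"))
        params = ParamSet(default_eta=0.0)
        results = match(rule, sent, params,
                        sub_event_tokens=frozenset({2}))
        assert len(results) == 1
        assert results[0].total == 0.0
        assert results[0].mapping == {20: 1, 23: 2}

    def test_inclusive_threshold_admits_boundary_distance(self):
        rule = simple_rule([Token(1, "a", "a", "NN"),
                            Token(2, "b", "b", "NN")],
                           [DepEdge(1, 2, "prep_of")])
        sent = DepGraph()
        sent.add_token(Token(1, "a", "a", "NN"))
        sent.add_token(Token(2, "b", "b", "NN"))
        sent.add_edge(DepEdge(1, 2, "prep_in"))
        params = ParamSet(w_s=10, w_l=10, w_d=10)
        # distance exactly 10 (label component 1.0)
        assert match(rule, sent, params, eta=10.0)
        assert not match(rule, sent, params, eta=9.99)

    @pytest.mark.parametrize("seed", range(60))
    def test_zero_threshold_equals_exact_embedding_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        rule, sent = random_instance(rng, max_rule=6, max_sentence=18)
        params = ParamSet(default_eta=0.0)
        got = {tuple(sorted(m.mapping.items()))
               for m in match(rule, sent, params)}
        want = {tuple(sorted(m.items()))
                for m in brute_force_exact_matches(rule, sent, PSL)}
        assert got == want

    @pytest.mark.parametrize("seed", range(30))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(2000 + seed)
        rule, sent = random_instance(rng, max_rule=5, max_sentence=14)
        params = ParamSet()
        sets = []
        for eta in (0.0, 3.0, 7.0, 15.0):
            sets.append({tuple(sorted(m.mapping.items()))
                         for m in match(rule, sent, params, eta=eta)})
        for small, big in zip(sets, sets[1:]):
            assert small <= big

    @pytest.mark.parametrize("seed", range(30))
    def test_components_nonnegative_and_normalized(self, seed):
        rng = np.random.default_rng(3000 + seed)
        rule, sent = random_instance(rng, max_rule=5, max_sentence=14)
        params = ParamSet()
        for m in match(rule, sent, params, eta=1e9):
            assert m.struct_d >= 0
            assert 0.0 <= m.label_d <= 1.0
            assert 0.0 <= m.dir_d <= 1.0
            assert m.total == pytest.approx(
                10 * m.struct_d + 10 * m.label_d + 10 * m.dir_d)
            if m.total == 0.0:
                assert m.struct_d == m.label_d == m.dir_d == 0.0

    def test_huge_threshold_admits_all_connected_feature_mappings(self):
        """With the threshold above any attainable cost, matching reduces
        to co-occurrence of the rule nodes (modulo connectivity)."""
        rng = np.random.default_rng(77)
        rule, sent = random_instance(rng, max_rule=4, max_sentence=10)
        params = ParamSet()
        got = {tuple(sorted(m.mapping.items()))
               for m in match(rule, sent, params, eta=1e9)}
        want = set()
        for m in brute_force_mappings(rule, sent, PSL):
            if not math.isinf(struct_dist(rule, sent, m)):
                want.add(tuple(sorted(m.items())))
        assert got == want
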