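"""Rule induction: argument paths, union/individual variants, corpus dedup."""

import itertools

import pytest

from asmevents.depgraph import DepEdge, DepGraph, Token
from asmevents.rules import (ArgSpec, ENTITY, SUB_EVENT, argument_paths,
                             induce_corpus, induce_rules, read_rules_jsonl,
                             rule_from_dict, rule_to_dict, rules_for_event,
                             rule_variants, write_rules_jsonl)

from helpers import make_doc


def edge_labels(rule):
    return sorted(e.label for e in rule.graph.edges)


class TestArgumentPaths:
    def test_single_path(self, reg_example_graph):
        bundles = argument_paths(reg_example_graph, [20], 23)
        assert len(bundles) == 1
        ((path,),) = bundles
        assert path.edges[0].label == "prep_to"

    def test_parallel_edges_give_two_bundles(self, reg_example_graph):
        bundles = argument_paths(reg_example_graph, [20], 6)
        assert len(bundles) == 2
        assert {b[0].edges[0].label for b in bundles} == {"nsubj", "rcmod"}

    def test_multi_token_trigger_merges_per_token_choices(self):
        # triggers {1,2} each with one path to argument 3
        g = DepGraph()
        for i in range(1, 4):
            g.add_token(Token(i, f"w{i}"))
        g.add_edge(DepEdge(1, 3, "dep_a"))
        g.add_edge(DepEdge(2, 3, "dep_b"))
        bundles = argument_paths(g, [1, 2], 3)
        assert len(bundles) == 1  # Cartesian of 1x1
        assert len(bundles[0]) == 2  # one path per trigger token

    def test_disconnected_argument_yields_nothing(self):
        g = DepGraph()
        g.add_token(Token(1, "a"))
        g.add_token(Token(2, "b"))
        assert argument_paths(g, [1], 2) == []


class TestRuleVariants:
    def _paths(self, g, trigger, arg):
        return argument_paths(g, [trigger], arg)

    def test_one_theme_path_two_cause_paths_give_five_rules(
            self, reg_example_graph):
        g = reg_example_graph
        rules = rules_for_event(g, "Positive_regulation", [20],
                                [ArgSpec("Theme", 23, SUB_EVENT),
                                 ArgSpec("Cause", 6, SUB_EVENT)])
        assert len(rules) == 5
        unions = [r for r in rules if r.variant == "union"]
        individuals = [r for r in rules if r.variant == "individual"]
        assert len(unions) == 2 and len(individuals) == 3
        assert sorted(map(edge_labels, unions)) == [
            ["nsubj", "prep_to"], ["prep_to", "rcmod"]]
        assert sorted(map(edge_labels, individuals)) == [
            ["nsubj"], ["prep_to"], ["rcmod"]]

    def test_single_argument_yields_individual_only(self, chain_graph):
        rules = rules_for_event(chain_graph, "Gene_expression", [1],
                                [ArgSpec("Theme", 3, ENTITY)])
        assert len(rules) == 1
        assert rules[0].variant == "individual"

    @pytest.mark.parametrize("n_theme,n_cause", [(1, 2), (2, 1), (2, 2)])
    def test_rule_count_formula(self, n_theme, n_cause):
        """k-role events produce prod(n_i) unions + sum(n_i) individuals
        (minus duplicates), checked against direct enumeration."""
        g = DepGraph()
        g.add_token(Token(10, "trig", "trig", "VBZ"))
        g.add_token(Token(11, "theme", "theme", "NN"))
        g.add_token(Token(12, "cause", "cause", "NN"))
        for k in range(n_theme):
            g.add_edge(DepEdge(10, 11, f"t{k}"))
        for k in range(n_cause):
            g.add_edge(DepEdge(10, 12, f"c{k}"))
        rules = rules_for_event(g, "Regulation", [10],
                                [ArgSpec("Theme", 11, ENTITY),
                                 ArgSpec("Cause", 12, ENTITY)])
        expected = n_theme * n_cause + n_theme + n_cause
        assert len(rules) == expected
        # cross-check against brute enumeration of the stated construction
        theme_paths = [f"t{k}" for k in range(n_theme)]
        cause_paths = [f"c{k}" for k in range(n_cause)]
        unions = set(itertools.product(theme_paths, cause_paths))
        individuals = set(theme_paths) | set(cause_paths)
        assert len(rules) == len(unions) + len(individuals)

    def test_entity_arguments_masked(self, chain_graph):
        (rule,) = rules_for_event(chain_graph, "Gene_expression", [1],
                                  [ArgSpec("Theme", 3, ENTITY)])
        assert rule.graph.token(3).is_entity
        assert rule.graph.token(3).surface == "site"  # surface retained
        assert not rule.graph.token(1).is_entity

    def test_trigger_argument_collision_dropped_when_other_args_exist(self):
        g = DepGraph()
        g.add_token(Token(1, "t", "t", "NN"))
        g.add_token(Token(2, "p", "p", "NN"))
        g.add_edge(DepEdge(1, 2, "prep_of"))
        rules = rules_for_event(g, "Binding", [1],
                                [ArgSpec("Theme", 1, ENTITY),
                                 ArgSpec("Theme2", 2, ENTITY)])
        assert len(rules) == 1
        assert rules[0].slots[0].role == "Theme2"

    def test_trigger_argument_collision_alone_gives_single_node_rule(self):
        g = DepGraph()
        g.add_token(Token(1, "t", "t", "NN"))
        rules = rules_for_event(g, "Gene_expression", [1],
                                [ArgSpec("Theme", 1, ENTITY)])
        assert len(rules) == 1 and len(rules[0].graph) == 1

    def test_all_rule_graphs_connected_and_contain_slots(
            self, reg_example_graph):
        rules = rules_for_event(reg_example_graph, "Positive_regulation",
                                [20], [ArgSpec("Theme", 23, SUB_EVENT),
                                       ArgSpec("Cause", 6, SUB_EVENT)])
        for r in rules:
            nodes = set(r.graph.tokens)
            assert r.trigger_nodes <= nodes
            assert all(s.node in nodes for s in r.slots)
            for u in nodes:
                for v in nodes:
                    assert r.graph.shortest_path_length(u, v) is not None


class TestInduceRules:
    def test_simple_expression_event(self):
        """Hand trace on a 3-token sentence: one rule with a masked
        entity node."""
        doc = make_doc("D", [{
            "tokens": [("expression", "NN"), ("of", "IN"), ("P", "NN")],
            "edges": [(1, 3, "prep_of")],
            "entities": {"T1": 3},
            "triggers": {"T2": ("Gene_expression", 1)},
            "events": [("E1", "Gene_expression", "T2", [("Theme", "T1")])],
        }])
        rules = induce_rules(doc)
        assert len(rules) == 1
        (rule,) = rules
        assert rule.event_type == "Gene_expression"
        assert rule.graph.token(3).is_entity
        assert rule.provenance == [("D", "D.s0", "E1")]

    def test_document_without_events_gives_no_rules(self):
        doc = make_doc("D", [{"tokens": [("a", "NN")]}])
        assert induce_rules(doc) == []

    def test_corpus_dedup_merges_provenance(self):
        spec = {
            "tokens": [("expression", "NN"), ("of", "IN"), ("P", "NN")],
            "edges": [(1, 3, "prep_of")],
            "entities": {"T1": 3},
            "triggers": {"T2": ("Gene_expression", 1)},
            "events": [("E1", "Gene_expression", "T2", [("Theme", "T1")])],
        }
        rules = induce_corpus([make_doc("D1", [spec]), make_doc("D2", [spec])])
        assert len(rules) == 1
        assert {p[0] for p in rules[0].provenance} == {"D1", "D2"}

    def test_sub_event_slots_flagged(self):
        doc = make_doc("D", [{
            "tokens": [("A", "NN"), ("induces", "VBZ", "induce"),
                       ("expression", "NN"), ("of", "IN"), ("B", "NN")],
            "edges": [(2, 1, "nsubj"), (2, 3, "dobj"), (3, 5, "prep_of")],
            "entities": {"T1": 1, "T2": 5},
            "triggers": {"T3": ("Gene_expression", 3),
                         "T4": ("Positive_regulation", 2)},
            "events": [("E1", "Gene_expression", "T3", [("Theme", "T2")]),
                       ("E2", "Positive_regulation", "T4",
                        [("Theme", "E1"), ("Cause", "T1")])],
        }])
        reg_rules = [r for r in induce_rules(doc)
                     if r.event_type == "Positive_regulation"]
        assert reg_rules
        for r in reg_rules:
            for slot in r.slots:
                if slot.role == "Theme":
                    assert slot.kind == SUB_EVENT
                    assert slot.node in r.sub_event_nodes
                    # sub-event trigger keeps its lexical features stored
                    assert r.graph.token(slot.node).lemma == "expression"


class TestSerialization:
    def test_jsonl_round_trip(self, tmp_path, reg_example_graph):
        rules = rules_for_event(reg_example_graph, "Positive_regulation",
                                [20], [ArgSpec("Theme", 23, SUB_EVENT),
                                       ArgSpec("Cause", 6, SUB_EVENT)])
        for i, r in enumerate(rules):
            r.rule_id = f"r{i}"
            r.provenance = [("D", "D.s0", "E1")]
        path = tmp_path / "rules.jsonl"
        write_rules_jsonl(rules, path)
        back = read_rules_jsonl(path)
        assert [r.canonical_key() for r in back] == \
            [r.canonical_key() for r in rules]
        assert [r.rule_id for r in back] == [r.rule_id for r in rules]

    def test_dict_round_trip_preserves_flags(self, chain_graph):
        (rule,) = rules_for_event(chain_graph, "Gene_expression", [1],
                                  [ArgSpec("Theme", 3, ENTITY)])
        rule.rule_id = "r1"
        back = rule_from_dict(rule_to_dict(rule))
        assert back.graph.token(3).is_entity
        assert back.graph.token(1).is_trigger
        assert back.slots == rule.slots
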