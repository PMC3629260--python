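import pytest

from asmevents.depgraph import DepEdge, DepGraph, Token


@pytest.fixture
def reg_example_graph():
    """Three-token dependency fragment of a Positive_regulation context:
    two parallel connections between the trigger verb and the cause noun
    plus one trigger→theme edge."""
    g = DepGraph(sentence_id="s0")
    g.add_token(Token(6, "ligation", "ligation", "NN"))
    g.add_token(Token(20, "lead", "lead", "VBP"))
    g.add_token(Token(23, "phosphorylation", "phosphorylation", "NN"))
    g.add_edge(DepEdge(20, 6, "nsubj"))
    g.add_edge(DepEdge(6, 20, "rcmod"))
    g.add_edge(DepEdge(20, 23, "prep_to"))
    return g


@pytest.fixture
def chain_graph():
    """a→b→c chain with lexical features."""
    g = DepGraph(sentence_id="chain")
    for i, (s, p) in enumerate([("binding", "NN"), ("of", "IN"),
                                ("site", "NN")], start=1):
        g.add_token(Token(i, s, s, p))
    g.add_edge(DepEdge(1, 2, "prep"))
    g.add_edge(DepEdge(2, 3, "pobj"))
    return g
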