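# asmevents

Approximate subgraph matching over dependency graphs for biomedical event
and relation extraction.

## The problem

Biomedical text-mining systems extract *events* — typed relations such as
`Positive_regulation(Theme: Phosphorylation(Theme: PROT1), Cause: PROT2)` —
from sentences whose syntax has been parsed into dependency graphs: nodes
are tokens, directed labeled edges are governor→dependent grammatical
relations (`nsubj`, `dobj`, collapsed prepositions like `prep_to`).
Instance-based extractors learn, from each annotated event, the subgraph of
dependencies connecting the event trigger to its arguments, and re-apply
those subgraphs as rules on unseen sentences.  Exact subgraph matching is
precise but brittle: a single changed preposition, a flipped edge, or one
extra token on a path hides the event.  This package implements an
**approximate subgraph matching (ASM)** framework that tolerates bounded
amounts of exactly this variation.

It is aimed at researchers working with BioNLP-ST–style standoff corpora
(`.txt`/`.a1`/`.a2` plus per-sentence parses) and at anyone who needs a
transparent, rule-level-debuggable event extractor.

## The method

**Rule induction.**  For every annotated event, the shortest paths (all of
them, in the undirected view of the sentence graph) from the trigger to
each argument are extracted.  Entity arguments are masked as `BIO_Entity`;
arguments that are themselves events are anchored at the sub-event's
trigger token.  Each event yields *path-union* rules (one per combination
of path choices across roles, capturing all arguments jointly) and
*individual-path* rules (one per role and path, matched independently and
later regrouped by shared trigger).

**Matching.**  A rule graph G_r matches a sentence graph G_s when an
injective node mapping f exists with

    subgraphDist(G_r, G_s) = w_s·structDist + w_l·labelDist + w_d·directionalityDist ≤ η

where, over every unordered pair of rule nodes, `structDist` accumulates
|shortest-path-length differences| (normalized by the rule-side path
lengths), and `labelDist` / `directionalityDist` count edge-label and
edge-orientation disagreements on the compared shortest paths (multiset
symmetric difference, normalized to [0, 1]).  η = 0 is exact subgraph
matching (ESM); larger per-event-type thresholds η_t buy recall at a
controlled precision cost.  Node pairs are admitted by configurable
criteria (default `P*+L`: relaxed POS word-class plus lemma identity).

**Assembly and pruning.**  Events are assembled bottom-up: simple events
first, then complex rules whose sub-event slots may bind any token that
triggers an already-extracted event, iterated to a fixpoint.  Finally each
rule is scored on the training corpus with its origin sentence left out,
and predicting rules whose TP:FP ratio falls below 1:4 are pruned,
iterating because removing a rule can strip dependent nested-event rules
of their support.

## Worked example

A `Positive_regulation` event whose trigger (`lead-20/VBP`) is connected to
its cause (`ligation-6/NN`) by two parallel dependencies and to its theme
(`phosphorylation-23/NN`) by one:

```python
from asmevents import DepGraph, DepEdge, Token, ParamSet, match
from asmevents.rules import ArgSpec, SUB_EVENT, rules_for_event

g = DepGraph(sentence_id="train")
g.add_token(Token(6, "ligation", "ligation", "NN"))
g.add_token(Token(20, "lead", "lead", "VBP"))
g.add_token(Token(23, "phosphorylation", "phosphorylation", "NN"))
g.add_edge(DepEdge(20, 6, "nsubj"))
g.add_edge(DepEdge(6, 20, "rcmod"))
g.add_edge(DepEdge(20, 23, "prep_to"))

rules = rules_for_event(g, "Positive_regulation", [20],
                        [ArgSpec("Theme", 23, SUB_EVENT),
                         ArgSpec("Cause", 6, SUB_EVENT)])
```

prints, when enumerated:

```
5 rules induced:
  [0] union      prep_to(20,23), nsubj(20,6)
  [1] union      prep_to(20,23), rcmod(6,20)
  [2] individual prep_to(20,23)
  [3] individual nsubj(20,6)
  [4] individual rcmod(6,20)
```

— two unions (one per trigger↔cause path, the theme path being unique) and
three individual trigger–argument paths.  Matching the theme rule against
an unseen sentence `leads-1 →prep_of→ phosphorylation-2` (different
preposition, conjugated verb):

```
eta= 0.0: no match (exact matching rejects prep_of vs prep_to)
eta=10.0: mapping {20: 1, 23: 2}, distance = 10x0.00 + 10x1.00 + 10x0.00 = 10.0
```

The swapped preposition costs two differing labels on a two-label
comparison (`labelDist` = 1.0); with equal weights of 10 the event is
recovered once η_t reaches 10.

## Command line

```
asmevents simulate --seed 7 --out corpus/          # synthetic annotated corpus
asmevents induce   --corpus corpus/ --out rules.jsonl
asmevents optimize --rules rules.jsonl --corpus corpus/ --out pruned.jsonl
asmevents extract  --rules pruned.jsonl --corpus corpus/ --out pred/
asmevents evaluate --pred pred/ --gold corpus/ --mode strict
asmevents tune     --train corpus/ --dev corpus/ --budget 50x100 --seed 1 --out params.yaml
```

The synthetic generator plants nested gold events in seeded dependency
corpora with controlled perturbations (node insertions, edge relabelings,
direction flips), so the whole pipeline is testable without downloads.

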