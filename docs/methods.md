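# Methods

This note records the model implemented by `asmevents`, the parameters
that matter, the numerical and design choices made where the design was
genuinely open, what the synthetic corpus generator does and does not
emulate, and the known limitations.

## Graph model

A sentence is a labeled, directed multigraph over 1-based token positions.
Collapsed-style dependencies are assumed: prepositions may fold into edge
labels (`prep_of`), which produces parallel edges and cycles; both are
supported throughout.  Copy tokens of the collapsed dialect (`word-6'`)
are materialized as distinct nodes at `index + 10000·k` so that injective
mappings treat them as separate words; whether such copies occurred in the
original setting is unknowable from the outputs, so this is a package
convention.

All shortest-path machinery runs on the **undirected** view of the graph,
with every parallel edge counted as a distinct length-1 connection;
directionality is scored separately by the matcher.  `shortest_path_length`
returns `None` for disconnected pairs; the matcher converts that to an
infinite distance, i.e. candidate rejection.

## Rule induction

For each annotated event the shortest path(s) from every trigger token to
each argument token are extracted (entity arguments at the entity head;
sub-event arguments at the sub-event trigger head, defined as the last
covered token of a multi-token trigger).  If several shortest paths exist,
all are kept.  For multi-token triggers, each path bundle combines one
path choice per trigger token (Cartesian product across per-token sets).

Two rule families are built per event:

* **union** variants: one rule per element of the Cartesian product across
  the roles' path-bundle sets; the rule graph is the path union, so all
  arguments are recognized jointly;
* **individual** variants: one rule per (role, bundle).

Single-argument events produce individual variants only (a union would
duplicate them); duplicates by canonical graph+slot form are collapsed.  A
zero-length trigger=argument path survives only when the event has no
other argument — a single-node graph carries no matchable context
otherwise.  Entity slot nodes are masked (`BIO_Entity`): the mask is
virtual, original surfaces are retained for reporting.  Sub-event slot
nodes keep their stored lexical features but are flagged; the *matcher*
relaxes them (below), keeping stored rules reusable under either reading.

Rules are deduplicated corpus-wide on (event type, canonical graph form,
slot structure) with all provenances retained.  Deduplication interacts
with leave-origin-out evaluation: a context recurring identically in k
sentences yields one rule whose k origin sentences are all excluded when
that rule is scored.

## Subgraph distance

For an injective mapping f from rule nodes to sentence nodes,

    total = w_s·structDist + w_l·labelDist + w_d·directionalityDist,

iterating over all C(n,2) unordered rule-node pairs (not only edges):

* `structDist` = Σ |d_r(u,v) − d_s(f(u),f(v))| / Σ d_r(u,v), with d the
  undirected shortest-path length in the respective graph.  Single-node
  rules score 0.  A sentence-disconnected pair rejects the candidate.
* `labelDist`: per pair, the multiset symmetric difference between the
  edge-label multisets of the compared shortest paths, summed and divided
  by the total number of labels on both paths — so a single swapped
  preposition on a length-1 path counts two differing labels and
  normalizes to 1.  Always in [0, 1].
* `directionalityDist`: identical construction over edge orientations,
  encoded forward/backward relative to the traversal from the
  lower-indexed endpoint of the rule pair (and the corresponding traversal
  of its image).

When a pair admits several shortest paths (parallel edges), one rule path
and one sentence path are selected jointly to minimize label +
orientation disagreement, ties broken by lexicographically smallest node
sequence — the most favorable deterministic reading, which guarantees that
a context identical up to parallel-edge alternatives still scores 0.

Threshold semantics are inclusive (`total ≤ η_t`), so η = 0 admits exact
matches.  Zero total under these definitions demands pairwise-distance
preservation, which is slightly stricter than classical edge-preserving
subgraph isomorphism whenever the sentence contains shortcuts between
non-adjacent rule-node images; the test-suite oracle checks exactly the
distance-preserving reading, and the discrepancy is a documented property
of the distance, not a bug.

The normalization denominators (rule-side path-length sum; both-side label
counts) were chosen to make each component scale-free in rule size and to
keep the label/orientation components in [0, 1]; they are validated by the
property suite, and the shipped default thresholds are calibrated to them.

## Node-match criteria

Criteria are conjunctions over: `P` exact POS; `P*` relaxed POS
(singular/plural nouns collapse, verb conjugations collapse, adjective and
adverb grades collapse); `L` lemma (case-insensitive; missing lemmas are a
configuration error, lemmatization is a pluggable upstream concern); `A`
exact token; `T` known-trigger — the sentence token's lemma must occur in
a lexicon collected from training triggers (the lexicon is the package's
own definition of this feature; its source is otherwise unspecified).
`BIO_Entity` rule nodes match exactly the entity-flagged sentence tokens,
skipping lexical checks.  Default: `P*+L`.

## Matching algorithm

Each rule has one start node: its lowest-indexed `BIO_Entity` node, else
its lowest-indexed node.  Sentence start candidates are all entity tokens
(entity-start rules) or all tokens.  For each feature-compatible start
pair, candidate lists for the remaining rule nodes are built and all
complete injective mappings are enumerated recursively in deterministic
ascending order.  Worst-case enumeration is exponential; a guard
(`scheme_cap`, default 100 000 schemes per start pair) aborts pathological
start pairs with a warning.  Mappings whose weighted distance is within
the event type's threshold are returned, deduplicated.

## Bottom-up event assembly

Rules without sub-event slots ("simple") are matched first.  Complex rules
are then matched in rounds in which a sub-event slot node may map onto
*any* token triggering an already-extracted event, its lexical features
ignored (`relax_sub_events=False` restores the strict lexical reading).
Arguments found by individual-variant matches that share (event type,
trigger tokens) are grouped into one merged candidate per filler
combination; multi-theme `Binding` events arise from this merge, and
groups with no Theme emit nothing.  Union-variant matches contribute their
events directly; both pathways are emitted and deduplicated, since neither
is given precedence.  A filler whose recursive closure already contains
the host's (type, trigger) pair is skipped, which both prevents
self-nesting and bounds the candidate space, so the fixpoint terminates; a
20-round cap remains as a safety net.  Iteration stops when a round adds
no new candidate event.

## Scoring

`strict` counts a prediction as true positive iff event type, trigger
token set and the full recursive argument structure match a gold event
(`Theme2`/`Theme3` normalize to `Theme`).  `approx_span` additionally
allows trigger spans to differ by one token on each side, recursively.
The official shared-task online metric is external and is not reimplemented.

## Rule-set optimization

`rule_stats` scores one rule alone on every training sentence except its
origin sentence(s); for complex rules, *gold* sub-events substitute as
fillers, isolating the rule's quality from other rules' errors.

`optimize_ruleset` iterates: full leave-origin-out pipeline extraction
with the current rule set (each sentence is matched by the rules not
induced from it; every prediction is credited to all source rules), then
removal of predicting rules with TP:FP < ρ (default 0.25, i.e. 1:4);
silent rules are always kept.  Using the pipeline's own predictions —
rather than gold substitutes — inside the iteration is deliberate: it is
what makes removal propagate, since pruning a simple rule can strip a
dependent regulation rule of its true positives one iteration later.
Convergence needs at most |ruleset| iterations.

## Parameter search

Thresholds (one per event type present) and optionally the three weights
are encoded as integers in [0, 50] and tuned to maximize strict F on a
development corpus: either exhaustively (`grid`, small spaces) or with a
seeded genetic algorithm (default budget 50 generations × population 100).
GA internals are this package's choices, not prescribed: tournament
selection (k = 2), uniform crossover (p = 0.5), per-gene mutation
(p = 0.1), elitism 1.  Ties prefer the smallest thresholds, then the
smallest weights — the most conservative matcher at equal fitness.  The
shipped default profile uses equal weights w_s = w_l = w_d = 10 and
per-type thresholds between 3 (regulation types) and 10.

## Synthetic corpus generator

`generate_corpus` emulates what the pipeline consumes: tokenized sentences
with POS and lemma, collapsed-style dependency trees, `Protein` entity
annotations, and nested gold events (regulations wrapping simple events,
with optional Cause).  Sentence graphs are trees over content tokens plus
optional *parallel* edges — a second, reversed connection labeled
`par_<base>` between already-adjacent tokens — which create multiple
shortest paths (exercising the all-paths branches of induction and the
path-selection branches of the distance) without changing any pairwise
distance.  Because the rule context of every planted event is a subtree,
an unperturbed corpus is exactly self-recoverable at η = 0; this is by
construction, and the parallel-edge labels are derived from the base
relation precisely so that alternative analyses of different relations
cannot collide into spurious zero-distance argument anchors.  Unannotated
distractor fragments reuse trigger lemmas in event-like configurations,
giving the pruning stage genuine false positives to remove.

Default conditions: 50 documents × 3 sentences, at most 2 facts per
sentence, 40 % of facts wrapped in a regulation, 50 % of regulations
carrying a Cause, distractor rate 0.2, parallel-edge rate 0.15, all
perturbation rates 0.  Test and acceptance runs scale the document count
per scenario (30 documents for the perturbation study, 50 for
self-recovery); these sizes give stable behaviour at interactive runtimes.

`perturb` applies, per edge, at most one of: node insertion (splits the
edge, lengthening the path between its endpoints by exactly one), relabel
(swap to a different label from a pool), flip (reverse direction).  Gold
annotations are untouched.  The perturbation study induces rules from the
clean corpus and extracts from the perturbed one at increasing thresholds:
with equal weights of 10, a single relabel or flip on a short context
costs 5 and is recovered at η = 7, while exact matching (η = 0) loses
every perturbed context — the generator-scale analogue of the
approximate-vs-exact recall gap.

What the generator does **not** emulate: real biomedical lexical
distributions, parser error profiles, cross-sentence phenomena,
discontinuous or multi-token triggers, and site/location arguments.
Passing self-recovery and tolerance tests therefore demonstrates the
correctness of the machinery under controlled conditions, not corpus-level
performance on real text.

## Degenerate inputs and numerical notes

* Empty parse input → empty graph; empty rule set → no events; empty path
  set → empty union graph.
* All distances are rational with small denominators; comparisons use
  exact floats (no tolerance is needed at the scales involved, and tests
  assert with `pytest.approx` only for readability).
* Sub-token annotation spans expand to the covering token; character
  offsets are 0-based half-open.
* Cross-sentence events are dropped on read with a logged warning, per the
  single-sentence scope.
* CoNLL output of the synthetic writer is single-head and therefore lossy
  on parallel edges; the Stanford-dependency dialect plus token-table
  sidecar is the faithful round-trip format.

## Known limitations

* The enumeration guard (`scheme_cap`) makes worst-case behaviour
  predictable but means adversarial sentences can silently contribute no
  matches for one start pair (a warning is logged).
* Fixing the rule start node to the lowest-indexed (entity) node is
  assumed not to lose solutions; the enumeration-equivalence tests confirm
  this empirically on random instances, not by proof.
* Binding events merge all co-triggered themes into one event; the
  alternative pairwise-event reading is not emitted.
* Equivalence (`*`), modification (`M`) and secondary-argument standoff
  lines are ignored.
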