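# Methods

## The evaluation model

`hyeval` evaluates a biological hypothesis — a tree whose leaves are typed
molecular events and whose internal nodes are n-ary AND/OR/XOR operators —
against a knowledge base of curated event facts. Evaluation has three stages:

1. **Candidate retrieval.** For each hypothesized event, facts are retrieved
   whose actor and target match the event's participant references and whose
   perturbation context equals the event's context token exactly (`"wt"`
   when unspecified). Participant matching resolves `same_as` aliases to a
   canonical identifier and honours type restrictions by reflexive-transitive
   is-a subsumption over the ontology excerpt, so a reference to "RNA"
   accepts an entity typed "messenger RNA". Nothing else is filtered at this
   stage — a candidate with the wrong relation, location, or negation flag is
   retained *on purpose*, because those deviations carry rule penalties and
   excluding them would make the penalties unreachable.

2. **Rule scoring.** Each candidate is scored by the ordered rule set for
   the event's type. A rule tests one condition (actor type, target type,
   actor function, location, relation verb, negation agreement, evidence
   code) and contributes `points_if_true` or `points_if_false`. The
   candidate with the highest raw sum is selected and linked to the event;
   ties break to the lexicographically smallest fact id so results are
   deterministic. The event score is the winning raw sum divided by the rule
   set's maximum achievable score — a fraction-of-maximum normalization that
   makes scores comparable across event types with different rule counts.
   The maximum counts only positive contributions, with the negation rule
   contributing zero at best; for the shipped induction set this maximum is 5.
   If retrieval produced no candidates the event is **undecidable**: it has
   no raw score, no normalized score, and no linked fact. Undecidable is
   deliberately distinct from zero — absence of data is not contradiction.

3. **Aggregation.** Scores propagate bottom-up: AND sums its children and is
   undecidable if any child is (a conjunction cannot be settled while a
   conjunct has no data); OR takes the maximum over decidable children and
   is undecidable only when all branches are; XOR is undecidable if any
   child is, otherwise it returns the single supported child's score
   (supported = decidable with value > 0) when exactly one child is
   supported, else 0. The overall hypothesis score is the root value,
   unnormalized — a two-event conjunction of 0.8-scored events reports 1.6.
   This favours multi-event hypotheses with partial support; the report also
   carries a per-event mean as a clearly-labelled auxiliary figure, which
   would rank simpler hypotheses higher if used instead.

Scores are exact rationals (`fractions.Fraction`) throughout and convert to
floats only at the report and CLI boundaries, so sums and comparisons never
accumulate floating-point error.

## Design choices on open points

* **XOR semantics** were specified only as intent ("exactly one of the
  events must be true, else both are false"). The implemented reading —
  undecidable-propagating, 0 unless exactly one child is supported — is the
  deterministic interpretation closest to that intent; permutation
  invariance is property-tested.
* **Negated claims.** A leaf may hypothesize that an event does *not* occur
  (`negated_claim: true`). The negation rule then flips polarity: a negated
  fact confirms (+2 with the default pair) and an asserted fact contradicts
  (−2). To preserve fraction-of-maximum semantics — an ideal confirming
  candidate must still score exactly 1 — the normalization denominator for a
  negated claim includes the +2 agreement bonus (7 for the induction set).
  This whole branch is a reconstruction: the default rule sets and the
  worked fixtures never exercise it with a maximum other than its default.
* **Negative scores are not clamped.** An event whose best candidate is
  penalized below zero reports a negative normalized score, and a decidable
  root may be negative. Callers who want a floor at zero can apply one.
* **Cross-type candidates.** Whether retrieval should exclude facts of a
  different event type is not settled; this implementation retrieves them
  and lets the relation rule (and type rules) penalize the mismatch, which
  reproduces the worked traces.
* **Rule 3 asymmetry.** The induction set's actor-function rule is +1/0 —
  a missing transcription-factor-activity annotation costs nothing. This
  asymmetry is load-bearing: the worked Gal4p→GAL1 trace requires 4/5, not
  3/5.

## Rule sets

Only the induction ("induce") rule set is authoritative; the other six
event types ship *reconstructed* sets built from the same template — actor
type (±1), target type (±1), actor function (+1/0), location (±1), relation
(±1), negation (0/−2) — with event-appropriate arguments (e.g. transport:
transporter activity GO:0005215, membrane GO:0016020, relation
"transport"). They are marked `"reconstructed": true` in
`src/hyeval/data/default_rules.json` and are fully overridable: rule sets
are plain JSON validated at load, with `max_score` derived, never stored.
An `evidence_is` condition is implemented for evidence-weighted scoring but
appears in no default set, since the modelled data mostly lacks evidence
annotations. The identifier for "gene" follows the source convention
(SO:0000236) rather than the current Sequence Ontology assignment.

## Ontology handling

The term store holds an excerpt, not a release: terms referenced but never
defined are auto-created as bare roots with a warning, the is-a relation is
validated as a DAG at load (a cycle is a hard error naming a member), and
part-of edges are stored under a separate label queried via
`has_part_transitive` — they never participate in `is_a`, because mixing
edge semantics would silently change rule outcomes. CURIE prefixes are
lower-cased on input; local parts keep their case (Bio2RDF-style
identifiers are case-significant there). Subsumption is memoized ancestor
sets; the independent test oracle is plain breadth-first search.

## The GAL fixture

`hyeval.fixtures.build_gal_fixture()` encodes the yeast galactose network
at exactly the granularity the engine exercises: four induction facts
(Gal4p→GAL1, Gal3p→GAL2, Gal4p→GAL7, Gal80p→GAL7, all nuclear, wild-type),
one transport fact (Gal2p → galactose at the plasma membrane) constructed
to satisfy every positive transport condition, and three GAL1-promoter
binding facts (Mig1p, Spt15p with evidence eco:0000008, Gal4p — the blank
and filled evidence cells are intentional). Two divergences from curated
biology are deliberate modelling choices: Gal4p carries DNA binding but
*not* transcription factor activity, capping each induction event at 4/5
(0.8); and the GAL1 promoter region is represented by the `sgd:GAL1` gene
entity. No fact exists for Gal80p inhibiting Gal4p under the "GAL3
over-expressed" context, which is what makes that event — and its entire
AND branch — undecidable. The fixture ontology's compartment terms take
is-a parents only to "cellular component"; their containment in the cell is
expressed as part-of, so no part-of edge is abused as is-a.

## The random generator

`gen_random_kb(FixtureSpec(...))` produces deterministic-per-seed knowledge
bases for property tests: entities typed protein/gene/chemical from the
fixture ontology (proteins carry every rule-rewarded function), facts drawn
across the seven event types from per-type profiles (canonical relation,
participant kinds, rewarded location). `negation_rate` is the per-fact
negation probability; `annotation_completeness` below 1 randomly drops or
perturbs the location and relation. At completeness 1 every generated fact
is *ideal* for its type's default rules, which is how the
ideal-candidate-normalizes-to-1 invariant is exercised. The generator
emulates structural properties (typed participants, contexts, negation,
subsumption-reachable annotations), not biological plausibility: passing
property tests demonstrates algorithmic correctness on well-formed inputs,
not performance on real curation noise such as conflicting contexts,
missing types, or idiosyncratic identifiers.

## Problem sizes and numerics

The worked evaluations run on the 8-fact fixture and complete in
milliseconds. Property tests use random knowledge bases of up to 200 facts
and 30 entities, trees of depth ≤ 4 with fan-out ≤ 4, and 50-term random
DAGs with exhaustive ordered-pair checks — sizes chosen so each oracle
comparison is exhaustive rather than sampled. All score arithmetic is
exact-rational; no tolerances are needed anywhere in the pipeline, and test
assertions on scores are equality assertions.

## Serialization

Facts and entities round-trip through a frozen-column TSV dialect and
through N-Triples over a small fixed `hq:` predicate vocabulary; both are
reconstructions (the original store's schema was never published) and the
loader ignores unrecognized predicates with a count in the load log.
Hypotheses exchange as JSON documents (`data/hypothesis.schema.json`
documents the dialect; validation is native) with an N-Triples serializer
for linked-data parity. Evaluation reports emit JSON and N-Triples; in the
graph form, scores link to the hypothesis via *is-about*/*has-part* and to
supporting facts via *is-about*, so the graph is navigable data→hypothesis
and hypothesis→data. Report instance identifiers are deterministic hashes
of (hypothesis id, KB digest, rule-set digest); timestamps are UTC ISO-8601
and excluded from the hash.

## Known limitations

* No OWL reasoning beyond is-a/part-of transitive closure: no equivalence,
  restrictions, or disjointness, and no loading of full ontology releases.
* The query pattern language covers single-event questions with unbound,
  optionally type-restricted variables — not joins across events or
  arbitrary graph patterns.
* Six of the seven default rule sets are reconstructions; scores under them
  are only as meaningful as the template.
* Identity resolution trusts `same_as` assertions transitively; a wrong
  alias merges two entities silently (validation reports only structural
  problems).
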