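# hyeval

Rule-based evaluation of biological hypotheses against a knowledge base of
typed molecular events, with ontology subsumption, logical score
aggregation, and linked-data provenance.

## The problem

A systems biologist proposing a mechanism — "Gal4p induces GAL1
expression", "Gal2p transports galactose into the cell" — wants to know how
well existing curated evidence supports it, and *which* evidence. Checking
by hand means coordinating typed interaction records, ontology annotations,
perturbation contexts, and explicit negative results across every clause of
a possibly nested hypothesis. `hyeval` automates this: hypotheses are trees
of typed events joined by AND/OR/XOR; each event is scored against the
knowledge base by an event-type-specific rule set; scores aggregate through
the tree; and the output links every score back to the facts that produced
it.

## The model

A hypothesized event *e* of type *t* (one of protein–protein binding,
protein–nucleic-acid binding, activation, inhibition, induction,
repression, transport) retrieves candidate facts matching its actor *a*,
target *g*, and perturbation context *c*. The rule set R_t = (r_1 … r_k)
scores each candidate fact *f*:

    raw(e, f) = Σ_i  points_i(f),   points_i ∈ {points_if_true, points_if_false}

    score(e)  = max_f raw(e, f) / max(R_t),   max(R_t) = Σ_i max(points_i⁺, 0)

with the negation rule contributing 0 at best. If no candidate exists,
*e* is **undecidable** — distinct from scoring zero. Scores aggregate as

    AND: Σ children (undecidable if any child is)
    OR:  max over decidable children (undecidable iff all are)
    XOR: the single supported child's score, else 0

Participant and annotation matching uses reflexive-transitive is-a
subsumption over GO/ChEBI/SO/ECO excerpts, so a rule or query written
against "RNA" also accepts "messenger RNA".

## Worked example

```python
from hyeval.evaluate import evaluate_hypothesis
from hyeval.fixtures import build_gal_fixture, gal_regulation_hypothesis
from hyeval.scoring import default_rulesets

kb, store = build_gal_fixture()
report = evaluate_hypothesis(
    gal_regulation_hypothesis(), kb, default_rulesets(), store
)
```

Running `python examples/evaluate_regulation_hypothesis.py` prints:

```
hypothesis: Gal3p/Gal4p/Gal80p regulation of GAL gene expression
overall:    decidable, score 1.6
  e1: 4/5 points → 0.8  (best fact hqd:f001)
  e2: 4/5 points → 0.8  (best fact hqd:f002)
  e3: 4/5 points → 0.8  (best fact hqd:f003)
  e4: 4/5 points → 0.8  (best fact hqd:f003)
  e5: undecidable (no candidate data in its context)
  e6: 4/5 points → 0.8  (best fact hqd:f004)
```

Each induction event earns 4 of the induce rule set's 5 points (the actor
is a protein, the target a gene, the event nuclear, the relation "induce" —
but Gal4p lacks a transcription-factor-activity annotation, so the function
rule adds nothing): 0.8 per event. Event e5 hypothesizes Gal80p inhibiting
Gal4p under a GAL3-over-expression context for which no data exists, so its
whole AND branch is undecidable. The best decidable branch is the e2∧e3
conjunction, 0.8 + 0.8 = **1.6** — the overall hypothesis score, and a
pointer to the alternative with the strongest experimental support.

The other examples cover the transport hypothesis (scores exactly 1 — full
support), the unbound-variable promoter-binding query (three GAL1 binders,
one with an evidence code), custom rule-set overrides, and the random KB
generator. A thin CLI wraps the same library:

```
hyeval fixture --gal --out-dir fixture/
hyeval evaluate --ontology fixture/gal_terms.tsv --kb fixture/gal_facts.tsv \
    --entities fixture/gal_entities.tsv --hypothesis my_hypothesis.json
hyeval query --ontology ... --kb ... --entities ... \
    --event-type protein-nucleic-acid-binding --actor-var '?a' \
    --actor-type chebi:36080 --target sgd:GAL1 --context wt
```

## Layout

- `src/hyeval/ontology.py` — term store, is-a/part-of transitive closure
- `src/hyeval/kb.py` — entities, event facts, identity resolution, TSV and
  N-Triples dialects, validation diagnostics
- `src/hyeval/hypothesis.py` — hypothesis trees, JSON document format,
  N-Triples serializer
- `src/hyeval/query.py` — candidate retrieval and unbound-variable queries
- `src/hyeval/scoring.py` — rule sets, per-event scoring, shipped config
- `src/hyeval/evaluate.py` — AND/OR/XOR aggregation, linked reports
- `src/hyeval/fixtures.py` — the GAL fixture and random generators
- `src/hyeval/cli.py` — `hyeval evaluate | query | fixture | validate`
- `docs/methods.md` — model details, design choices, limitations
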