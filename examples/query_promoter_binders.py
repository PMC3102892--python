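"""Ask an open question: which proteins bind the GAL1 promoter in wild type?

The actor is an unbound, type-restricted variable — no specific protein is
named — and the evidence field is a second variable, so each answer row
carries the evidence code supporting it (blank where the knowledge base
records none).  Type restriction uses ontology subsumption, so a query for
'protein' would also match entities typed with any protein subclass.
"""

from hyeval.fixtures import build_gal_fixture
from hyeval.hypothesis import EntityRef
from hyeval.query import EventPattern, query_events, result_to_tsv

kb, store = build_gal_fixture()
pattern = EventPattern(
    event_type="protein-nucleic-acid-binding",
    actor=EntityRef.unbound("?protein", "chebi:36080"),
    target=EntityRef.instance("sgd:GAL1"),
    context="wt",
    evidence="?evidence",
)
result = query_events(pattern, kb, store)

print(f"{len(result.rows)} binder(s) found:")
for row in result.rows:
    b = row.as_dict()
    print(f"  {b['?protein']:14s} evidence: {b['?evidence'] or '(none recorded)'}")
print()
print(result_to_tsv(result, kb, store))

# Three proteins bind the GAL1 promoter in wild-type yeast; only the
# Spt15p interaction carries an explicit evidence-code annotation.
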