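"""The GAL-network fixture knowledge base and random test-data generators.

The fixture encodes the yeast galactose (GAL) regulatory network at exactly
the granularity the evaluation engine exercises: Gal4p-driven induction of
the GAL structural genes, Gal2p-mediated galactose transport across the
plasma membrane, and the three proteins known to bind the GAL1 promoter in
wild-type cells (Mig1p, Spt15p — with an ECO evidence code — and Gal4p).

Deliberate modelling choices (divergences from curated SGD biology, made so
the rule traces come out as designed):

* Gal4p carries a DNA-binding annotation but **not** transcription factor
  activity (go:0003702), so the induce rule set's function rule scores 0
  and each induction event earns 4 of 5 points (0.8 normalized);
* the GAL1 promoter region is represented by the ``sgd:GAL1`` gene entity;
* no fact exists for Gal80p inhibiting Gal4p under the "GAL3
  over-expressed" perturbation, leaving that event undecidable;
* the Gal2p → galactose transport fact satisfies every positive condition
  of the default transport rule set, normalizing to exactly 1.

:func:`gen_random_kb` emits deterministic-per-seed knowledge bases for
property tests: entities typed from the fixture ontology, facts across the
seven event types, negation applied at ``negation_rate`` and
function/location annotations present at ``annotation_completeness`` (at
1.0 every generated fact is "ideal" for its event type's default rules).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .errors import DataError
from .hypothesis import Hypothesis, parse_hypothesis
from .kb import Entity, EventFact, KnowledgeBase, kb_to_entity_tsv, kb_to_fact_tsv, kb_to_ntriples
from .ontology import OntologyTerm, TermStore, load_terms

__all__ = [
    "FixtureSpec",
    "gal_ontology",
    "build_gal_fixture",
    "gal_regulation_hypothesis",
    "galactose_transport_hypothesis",
    "gen_random_kb",
    "write_gal_fixture",
]

_GAL_TERMS = [
    # id, label, is-a parents, part-of parents
    ("chebi:24431", "chemical entity", "", ""),
    ("chebi:36080", "protein", "chebi:24431", ""),
    ("chebi:33697", "ribonucleic acid", "chebi:24431", ""),
    ("chebi:33699", "messenger RNA", "chebi:33697", ""),
    ("chebi:16646", "carbohydrate", "chebi:24431", ""),
    ("chebi:28260", "galactose", "chebi:16646", ""),
    ("so:0000110", "sequence feature", "", ""),
    ("so:0000236", "gene", "so:0000110", ""),
    ("go:0005575", "cellular component", "", ""),
    ("go:0005623", "cell", "go:0005575", ""),
    ("go:0005634", "nucleus", "go:0005575", "go:0005623"),
    ("go:0005737", "cytoplasm", "go:0005575", "go:0005623"),
    ("go:0016020", "membrane", "go:0005575", "go:0005623"),
    ("go:0005886", "plasma membrane", "go:0016020", "go:0005623"),
    ("go:0003674", "molecular function", "", ""),
    ("go:0003702", "transcription factor activity", "go:0003674", ""),
    ("go:0003677", "DNA binding", "go:0003674", ""),
    ("go:0005515", "protein binding", "go:0003674", ""),
    ("go:0005215", "transporter activity", "go:0003674", ""),
    ("go:0004857", "enzyme inhibitor activity", "go:0003674", ""),
    ("eco:0000000", "evidence", "", ""),
    ("eco:0000008", "experimental assay evidence", "eco:0000000", ""),
]

_GAL_ENTITIES = [
    # id, name, types, functions, same_as
    ("sgd:Gal2p", "Gal2p", "chebi:36080", "go:0005215", ""),
    ("sgd:Gal3p", "Gal3p", "chebi:36080", "go:0005515", ""),
    ("sgd:Gal4p", "Gal4p", "chebi:36080", "go:0003677", "sgd:S000006169gp"),
    ("sgd:Gal80p", "Gal80p", "chebi:36080", "", ""),
    ("sgd:Mig1p", "Mig1p", "chebi:36080", "go:0003677", ""),
    ("sgd:Spt15p", "Spt15p", "chebi:36080", "go:0003677", ""),
    ("sgd:GAL1", "GAL1", "so:0000236", "", ""),
    ("sgd:GAL2", "GAL2", "so:0000236", "", ""),
    ("sgd:GAL7", "GAL7", "so:0000236", "", ""),
    ("chebi:28260", "galactose", "chebi:28260", "", ""),
]

_GAL_FACTS = [
    # id, event_type, relation, actor, target, location, context, evidence, negated, source
    ("hqd:f001", "induction", "induce", "sgd:Gal4p", "sgd:GAL1",
     "go:0005634", "wt", "", False, "pmid:6757714"),
    ("hqd:f002", "induction", "induce", "sgd:Gal3p", "sgd:GAL2",
     "go:0005634", "wt", "", False, "pmid:8321207"),
    ("hqd:f003", "induction", "induce", "sgd:Gal4p", "sgd:GAL7",
     "go:0005634", "wt", "", False, "pmid:6757714"),
    ("hqd:f004", "induction", "induce", "sgd:Gal80p", "sgd:GAL7",
     "go:0005634", "wt", "", False, "pmid:2160094"),
    ("hqd:f005", "transport", "transport", "sgd:Gal2p", "chebi:28260",
     "go:0005886", "wt", "", False, "pmid:2649880"),
    ("hqd:f006", "protein-nucleic-acid-binding", "bind", "sgd:Mig1p", "sgd:GAL1",
     "go:0005634", "wt", "", False, "pmid:1809833"),
    ("hqd:f007", "protein-nucleic-acid-binding", "bind", "sgd:Spt15p", "sgd:GAL1",
     "go:0005634", "wt", "eco:0000008", False, "pmid:2177471"),
    ("hqd:f008", "protein-nucleic-acid-binding", "bind", "sgd:Gal4p", "sgd:GAL1",
     "go:0005634", "wt", "", False, "pmid:6757714"),
]


def gal_ontology() -> TermStore:
    """The ontology excerpt covering every CURIE the fixture and rules use."""
    return load_terms(
        OntologyTerm(
            tid,
            label,
            tuple(p for p in parents.split("|") if p),
            tuple(p for p in part_of.split("|") if p),
        )
        for tid, label, parents, part_of in _GAL_TERMS
    )


def build_gal_fixture() -> tuple[KnowledgeBase, TermStore]:
    """Build the GAL knowledge base and its ontology store."""
    store = gal_ontology()
    kb = KnowledgeBase()
    for eid, name, types, functions, same_as in _GAL_ENTITIES:
        kb.add_entity(
            Entity(
                eid,
                name,
                tuple(t for t in types.split("|") if t),
                tuple(f for f in functions.split("|") if f),
                tuple(s for s in same_as.split("|") if s),
            )
        )
    kb.resolve_identities()
    for fid, etype, rel, actor, target, loc, ctx, ev, neg, src in _GAL_FACTS:
        kb.add_fact(
            EventFact(
                id=fid,
                event_type=etype,
                relation=rel,
                actor=actor,
                target=target,
                location=loc or None,
                context=ctx,
                evidence=ev or None,
                negated=neg,
                source=src or None,
            )
        )
    return kb, store


def gal_regulation_hypothesis() -> Hypothesis:
    """The worked six-event GAL regulation hypothesis.

    OR( e1: Gal4p induces GAL1,
        AND(e2: Gal3p induces GAL2, e3: Gal4p induces GAL7),
        AND(e4: Gal4p induces GAL7,
            e5: Gal80p inhibits Gal4p under GAL3 over-expression,
            e6: Gal80p induces GAL7) )
    """

    def induce(label: str, actor: str, target: str) -> dict:
        return {
            "event": {
                "label": label,
                "event_type": "induction",
                "relation": "induce",
                "actor": {"instance": actor},
                "target": {"instance": target},
                "location": "go:0005634",
            }
        }

    doc = {
        "id": "gal-regulation",
        "title": "Gal3p/Gal4p/Gal80p regulation of GAL gene expression",
        "root": {
            "operator": "OR",
            "children": [
                induce("e1", "sgd:Gal4p", "sgd:GAL1"),
                {
                    "operator": "AND",
                    "children": [
                        induce("e2", "sgd:Gal3p", "sgd:GAL2"),
                        induce("e3", "sgd:Gal4p", "sgd:GAL7"),
                    ],
                },
                {
                    "operator": "AND",
                    "children": [
                        induce("e4", "sgd:Gal4p", "sgd:GAL7"),
                        {
                            "event": {
                                "label": "e5",
                                "event_type": "inhibition",
                                "relation": "inhibit",
                                "actor": {"instance": "sgd:Gal80p"},
                                "target": {"instance": "sgd:Gal4p"},
                                "context": "GAL3 over-expressed",
                            }
                        },
                        induce("e6", "sgd:Gal80p", "sgd:GAL7"),
                    ],
                },
            ],
        },
    }
    return parse_hypothesis(doc)


def galactose_transport_hypothesis() -> Hypothesis:
    """Leaf-only hypothesis: Gal2p transports galactose into the cell."""
    doc = {
        "id": "galactose-transport",
        "title": "Gal2p transports galactose across the plasma membrane",
        "root": {
            "event": {
                "label": "e1",
                "event_type": "transport",
                "relation": "transport",
                "actor": {"instance": "sgd:Gal2p"},
                "target": {"instance": "chebi:28260"},
                "location": "go:0005886",
            }
        },
    }
    return parse_hypothesis(doc)


# ---------------------------------------------------------------------------
# random generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for deterministic random KB generation."""

    seed: int
    n_entities: int = 20
    n_facts: int = 40
    negation_rate: float = 0.1
    annotation_completeness: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.negation_rate <= 1:
            raise DataError("negation_rate must be in [0, 1]")
        if not 0 <= self.annotation_completeness <= 1:
            raise DataError("annotation_completeness must be in [0, 1]")


# per event type: canonical relation, actor/target entity kind, the
# function and location the default rule sets reward
_EVENT_PROFILES = {
    "induction": ("induce", "protein", "gene", "go:0003702", "go:0005634"),
    "repression": ("repress", "protein", "gene", "go:0003702", "go:0005634"),
    "transport": ("transport", "protein", "chemical", "go:0005215", "go:0005886"),
    "activation": ("activate", "protein", "protein", "go:0005515", "go:0005737"),
    "inhibition": ("inhibit", "protein", "protein", "go:0004857", "go:0005737"),
    "protein-protein-binding": ("bind", "protein", "protein", "go:0005515", "go:0005737"),
    "protein-nucleic-acid-binding": ("bind", "protein", "gene", "go:0003677", "go:0005634"),
}

_KIND_TYPES = {
    "protein": "chebi:36080",
    "gene": "so:0000236",
    "chemical": "chebi:28260",
}


def gen_random_kb(spec: FixtureSpec, store: TermStore) -> KnowledgeBase:
    """Generate a deterministic-per-seed random knowledge base.

    Entities are typed protein/gene/chemical; each fact is built from its
    event type's profile.  With ``annotation_completeness`` of 1 every fact
    fully satisfies the positive conditions of the default rule set for its
    type (an "ideal" fact); lower values randomly drop or perturb location
    and relation.  ``negation_rate`` sets the per-fact probability of the
    negation flag.
    """
    if spec.n_facts > 0 and spec.n_entities < 2:
        raise DataError("need at least 2 entities to generate facts")
    rng = random.Random(spec.seed)
    kb = KnowledgeBase()
    kinds = ["protein", "gene", "chemical"]
    entity_ids: dict[str, list[str]] = {k: [] for k in kinds}
    for i in range(spec.n_entities):
        kind = kinds[i % 3] if i < 6 else rng.choice(kinds)
        eid = f"hqd:ent{i:03d}"
        functions: tuple[str, ...] = ()
        if kind == "protein":
            # proteins carry every rewarded function so an ideal fact exists
            # for any event type; completeness perturbs location/relation
            functions = ("go:0003702", "go:0005215", "go:0005515",
                         "go:0004857", "go:0003677")
        kb.add_entity(Entity(eid, f"entity {i}", (_KIND_TYPES[kind],), functions))
        entity_ids[kind].append(eid)
    kb.resolve_identities()

    event_types = sorted(_EVENT_PROFILES)
    for j in range(spec.n_facts):
        etype = rng.choice(event_types)
        relation, actor_kind, target_kind, _func, location = _EVENT_PROFILES[etype]
        actors = entity_ids[actor_kind] or [
            eid for ids in entity_ids.values() for eid in ids
        ]
        targets = entity_ids[target_kind] or [
            eid for ids in entity_ids.values() for eid in ids
        ]
        actor = rng.choice(actors)
        target = rng.choice(targets)
        loc: str | None = location
        if rng.random() >= spec.annotation_completeness:
            loc = rng.choice([None, "go:0005737", "go:0005634"])
        if rng.random() >= spec.annotation_completeness:
            relation = rng.choice(["interact", relation])
        kb.add_fact(
            EventFact(
                id=f"hqd:fact{j:04d}",
                event_type=etype,
                relation=relation,
                actor=actor,
                target=target,
                location=loc,
                context="wt",
                negated=rng.random() < spec.negation_rate,
            )
        )
    return kb


def write_gal_fixture(out_dir: str | Path, store: TermStore | None = None) -> list[Path]:
    """Emit the fixture in both dialects; returns the written paths."""
    kb, kb_store = build_gal_fixture()
    store = store or kb_store
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, text in (
        ("gal_terms.tsv", store.to_tsv()),
        ("gal_entities.tsv", kb_to_entity_tsv(kb)),
        ("gal_facts.tsv", kb_to_fact_tsv(kb)),
        ("gal_kb.nt", kb_to_ntriples(kb, store)),
    ):
        path = out / name
        path.write_text(text)
        written.append(path)
    return written
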