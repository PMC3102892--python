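"""The event knowledge base: entities and typed molecular-event facts.

A :class:`KnowledgeBase` holds curated statements of the form *actor —
relation → target* for seven kinds of cellular events (protein–protein
binding, protein–nucleic-acid binding, activation, inhibition, gene
induction, gene repression, transport), each optionally carrying a cellular
location, a genetic perturbation context (``"wt"`` for wild type), an ECO
evidence code, a source citation, and a boolean negation flag asserting
that the event does *not* occur under the stated conditions.  A fact and
its negation may coexist — consumers (the scoring rules) decide what a
contradiction is worth.

Entity records carry ontology types (e.g. ``chebi:36080`` protein), GO
function annotations, and ``same_as`` aliases.  On load, alias groups are
resolved union-find style to a canonical identifier (the lexicographically
smallest member) so that facts naming any alias compare equal.

Two on-disk dialects round-trip losslessly:

* a frozen TSV fact dialect with columns ``fact_id, event_type, relation,
  actor, target, location, context, evidence, negated, source`` (and an
  entity TSV with ``id, name, types, functions, same_as``);
* N-Triples over a small fixed ``hq:`` predicate vocabulary (a documented
  reconstruction; unrecognized predicates are ignored and counted).
"""

from __future__ import annotations

import csv
import hashlib
import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import rdflib

from .errors import DataError
from .ontology import TermStore, contract_iri, expand_curie, normalize_curie

logger = logging.getLogger(__name__)

__all__ = [
    "EVENT_TYPES",
    "Entity",
    "EventFact",
    "KnowledgeBase",
    "Diagnostic",
    "load_kb",
    "validate_kb",
    "kb_to_fact_tsv",
    "kb_to_entity_tsv",
    "kb_to_ntriples",
]

EVENT_TYPES = frozenset(
    {
        "protein-protein-binding",
        "protein-nucleic-acid-binding",
        "activation",
        "inhibition",
        "induction",
        "repression",
        "transport",
    }
)

FACT_COLUMNS = (
    "fact_id",
    "event_type",
    "relation",
    "actor",
    "target",
    "location",
    "context",
    "evidence",
    "negated",
    "source",
)
ENTITY_COLUMNS = ("id", "name", "types", "functions", "same_as")

# hq: predicate vocabulary for the N-Triples dialect
_HQ = "http://example.org/hq/vocab#"
_RDF_TYPE = str(rdflib.RDF.type)
_OWL_SAME_AS = str(rdflib.OWL.sameAs)


@dataclass
class Entity:
    """A molecular entity (gene, gene product, small molecule)."""

    id: str
    name: str = ""
    types: tuple[str, ...] = ()
    functions: tuple[str, ...] = ()
    same_as: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.id = normalize_curie(self.id)
        self.types = tuple(normalize_curie(t) for t in self.types)
        self.functions = tuple(normalize_curie(f) for f in self.functions)
        self.same_as = tuple(normalize_curie(s) for s in self.same_as)


@dataclass(frozen=True)
class EventFact:
    """One (possibly negated) molecular-event record."""

    id: str
    event_type: str
    relation: str
    actor: str
    target: str
    location: str | None = None
    context: str = "wt"
    evidence: str | None = None
    negated: bool = False
    source: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "id", normalize_curie(self.id))
        object.__setattr__(self, "actor", normalize_curie(self.actor))
        object.__setattr__(self, "target", normalize_curie(self.target))
        if self.location:
            object.__setattr__(self, "location", normalize_curie(self.location))
        if self.evidence:
            object.__setattr__(self, "evidence", normalize_curie(self.evidence))
        if not self.context:
            object.__setattr__(self, "context", "wt")
        if self.event_type not in EVENT_TYPES:
            raise DataError(
                f"fact {self.id}: unknown event_type {self.event_type!r} "
                f"(expected one of {sorted(EVENT_TYPES)})"
            )


@dataclass(frozen=True)
class Diagnostic:
    level: str  # "error" | "warning" | "info"
    code: str
    message: str


class KnowledgeBase:
    """Entities plus facts with indexes by actor, target and context key."""

    def __init__(self) -> None:
        self.entities: dict[str, Entity] = {}
        self.facts: list[EventFact] = []
        self.aliases: dict[str, str] = {}  # alias CURIE -> canonical CURIE
        self.by_actor: dict[str, list[EventFact]] = {}
        self.by_target: dict[str, list[EventFact]] = {}
        self.by_key: dict[tuple[str, str, str], list[EventFact]] = {}

    def canonical(self, curie: str) -> str:
        curie = normalize_curie(curie)
        return self.aliases.get(curie, curie)

    def entity(self, curie: str) -> Entity:
        cid = self.canonical(curie)
        try:
            return self.entities[cid]
        except KeyError:
            raise DataError(f"unknown entity {curie!r}") from None

    def add_entity(self, entity: Entity) -> None:
        if entity.id in self.entities:
            raise DataError(f"duplicate entity id {entity.id!r}")
        self.entities[entity.id] = entity

    def add_fact(self, fact: EventFact) -> None:
        """Add a fact (actor/target rewritten to canonical ids) and index it."""
        fact = replace(
            fact, actor=self.canonical(fact.actor), target=self.canonical(fact.target)
        )
        for role, curie in (("actor", fact.actor), ("target", fact.target)):
            if curie not in self.entities:
                raise DataError(
                    f"fact {fact.id}: {role} {curie!r} is not a declared entity"
                )
        self.facts.append(fact)
        self.by_actor.setdefault(fact.actor, []).append(fact)
        self.by_target.setdefault(fact.target, []).append(fact)
        key = (fact.actor, fact.target, fact.context)
        self.by_key.setdefault(key, []).append(fact)

    def resolve_identities(self) -> None:
        """Collapse ``same_as`` groups onto canonical ids (idempotent).

        The canonical id of a group is its lexicographically smallest
        member; merged entities union their types/functions and list the
        remaining group members as aliases.
        """
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            root = x
            while parent.get(root, root) != root:
                root = parent[root]
            while parent.get(x, x) != x:
                parent[x], x = root, parent[x]
            return root

        def union(a: str, b: str) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                # keep the lexicographically smallest id as the root
                lo, hi = sorted((ra, rb))
                parent[hi] = lo

        for ent in self.entities.values():
            for alias in ent.same_as:
                union(ent.id, alias)
        for alias, canon in list(self.aliases.items()):
            union(alias, canon)

        groups: dict[str, set[str]] = {}
        for member in set(parent) | set(self.entities):
            groups.setdefault(find(member), set()).add(member)

        new_entities: dict[str, Entity] = {}
        new_aliases: dict[str, str] = {}
        for canon, members in groups.items():
            declared = [self.entities[m] for m in sorted(members) if m in self.entities]
            if not declared:
                continue
            types: list[str] = []
            functions: list[str] = []
            name = ""
            for ent in declared:
                name = name or ent.name
                types.extend(t for t in ent.types if t not in types)
                functions.extend(f for f in ent.functions if f not in functions)
            new_entities[canon] = Entity(
                canon,
                name,
                tuple(types),
                tuple(functions),
                tuple(sorted(members - {canon})),
            )
            for member in members - {canon}:
                new_aliases[member] = canon
        self.entities = new_entities
        self.aliases = new_aliases
        facts, self.facts = self.facts, []
        self.by_actor, self.by_target, self.by_key = {}, {}, {}
        for fact in facts:
            self.add_fact(fact)

    def digest(self) -> str:
        """Stable content hash of the canonical TSV serialization."""
        payload = (kb_to_entity_tsv(self) + kb_to_fact_tsv(self)).encode()
        return hashlib.sha256(payload).hexdigest()


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------


def _split(cell: str) -> tuple[str, ...]:
    return tuple(p for p in cell.split("|") if p.strip())


def _read_tsv(text: str, columns: tuple[str, ...], what: str) -> list[dict[str, str]]:
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    rows = [row for row in reader if row and any(c.strip() for c in row)]
    if not rows:
        return []
    header = [c.strip() for c in rows[0]]
    if header != list(columns):
        raise DataError(
            f"{what} TSV header mismatch: expected {list(columns)}, got {header}"
        )
    out = []
    for row in rows[1:]:
        row = list(row) + [""] * (len(columns) - len(row))
        out.append(dict(zip(columns, (c.strip() for c in row))))
    return out


def _parse_bool(token: str, where: str) -> bool:
    token = token.strip().lower()
    if token in ("", "false", "0"):
        return False
    if token in ("true", "1"):
        return True
    raise DataError(f"{where}: cannot parse boolean {token!r}")


def entities_from_tsv(text: str) -> list[Entity]:
    return [
        Entity(
            row["id"],
            row["name"],
            _split(row["types"]),
            _split(row["functions"]),
            _split(row["same_as"]),
        )
        for row in _read_tsv(text, ENTITY_COLUMNS, "entity")
    ]


def facts_from_tsv(text: str) -> list[EventFact]:
    return [
        EventFact(
            id=row["fact_id"],
            event_type=row["event_type"],
            relation=row["relation"],
            actor=row["actor"],
            target=row["target"],
            location=row["location"] or None,
            context=row["context"] or "wt",
            evidence=row["evidence"] or None,
            negated=_parse_bool(row["negated"], f"fact {row['fact_id']}"),
            source=row["source"] or None,
        )
        for row in _read_tsv(text, FACT_COLUMNS, "fact")
    ]


def kb_to_entity_tsv(kb: KnowledgeBase) -> str:
    lines = ["\t".join(ENTITY_COLUMNS)]
    for eid in sorted(kb.entities):
        e = kb.entities[eid]
        lines.append(
            "\t".join(
                (
                    e.id,
                    e.name,
                    "|".join(e.types),
                    "|".join(e.functions),
                    "|".join(e.same_as),
                )
            )
        )
    return "\n".join(lines) + "\n"


def kb_to_fact_tsv(kb: KnowledgeBase) -> str:
    lines = ["\t".join(FACT_COLUMNS)]
    for f in sorted(kb.facts, key=lambda f: f.id):
        lines.append(
            "\t".join(
                (
                    f.id,
                    f.event_type,
                    f.relation,
                    f.actor,
                    f.target,
                    f.location or "",
                    f.context,
                    f.evidence or "",
                    "true" if f.negated else "false",
                    f.source or "",
                )
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# N-Triples dialect
# ---------------------------------------------------------------------------


def kb_to_ntriples(kb: KnowledgeBase, store: TermStore | None = None) -> str:
    """Serialize entities and facts over the ``hq:`` predicate vocabulary."""
    pm = store.prefix_map if store is not None else _default_pm()
    g = rdflib.Graph()

    def uri(curie: str) -> rdflib.URIRef:
        return rdflib.URIRef(expand_curie(curie, pm))

    hq = rdflib.Namespace(_HQ)
    for eid in sorted(kb.entities):
        e = kb.entities[eid]
        s = uri(e.id)
        g.add((s, rdflib.RDF.type, hq.Entity))
        if e.name:
            g.add((s, rdflib.RDFS.label, rdflib.Literal(e.name)))
        for t in e.types:
            g.add((s, hq.entityType, uri(t)))
        for f in e.functions:
            g.add((s, hq.function, uri(f)))
        for a in e.same_as:
            g.add((s, rdflib.OWL.sameAs, uri(a)))
    for f in sorted(kb.facts, key=lambda f: f.id):
        s = uri(f.id)
        g.add((s, rdflib.RDF.type, hq.Event))
        g.add((s, hq.eventType, rdflib.Literal(f.event_type)))
        g.add((s, hq.relation, rdflib.Literal(f.relation)))
        g.add((s, hq.actor, uri(f.actor)))
        g.add((s, hq.target, uri(f.target)))
        if f.location:
            g.add((s, hq.location, uri(f.location)))
        g.add((s, hq.context, rdflib.Literal(f.context)))
        if f.evidence:
            g.add((s, hq.evidence, uri(f.evidence)))
        g.add((s, hq.isNegated, rdflib.Literal(f.negated)))
        if f.source:
            g.add((s, hq.source, rdflib.Literal(f.source)))
    return g.serialize(format="nt")


def _default_pm() -> dict[str, str]:
    from .ontology import default_prefix_map

    return default_prefix_map()


def _kb_sources_from_ntriples(text: str, pm: dict[str, str]):
    """Parse the hq: N-Triples dialect back into entity and fact lists."""
    g = rdflib.Graph()
    g.parse(data=text, format="nt")

    def curie(node: rdflib.term.Node) -> str | None:
        if isinstance(node, rdflib.URIRef):
            return contract_iri(str(node), pm)
        return None

    ent_rows: dict[str, dict] = {}
    fact_rows: dict[str, dict] = {}
    ignored = 0
    for s, p, o in g:
        sc = curie(s)
        if sc is None:
            ignored += 1
            continue
        pred = str(p)
        if pred == _RDF_TYPE and str(o) == _HQ + "Entity":
            ent_rows.setdefault(
                sc, {"name": "", "types": [], "functions": [], "same_as": []}
            )
        elif pred == _RDF_TYPE and str(o) == _HQ + "Event":
            fact_rows.setdefault(sc, {})
        elif pred.startswith(_HQ) or pred in (str(rdflib.RDFS.label), _OWL_SAME_AS):
            continue  # handled in the second pass below
        else:
            ignored += 1
    for s, p, o in g:
        sc = curie(s)
        if sc is None:
            continue
        pred = str(p)
        if sc in ent_rows:
            row = ent_rows[sc]
            if pred == str(rdflib.RDFS.label):
                row["name"] = str(o)
            elif pred == _HQ + "entityType":
                row["types"].append(curie(o))
            elif pred == _HQ + "function":
                row["functions"].append(curie(o))
            elif pred == _OWL_SAME_AS:
                row["same_as"].append(curie(o))
        elif sc in fact_rows:
            row = fact_rows[sc]
            local = pred[len(_HQ):] if pred.startswith(_HQ) else None
            if local == "eventType":
                row["event_type"] = str(o)
            elif local == "relation":
                row["relation"] = str(o)
            elif local == "actor":
                row["actor"] = curie(o)
            elif local == "target":
                row["target"] = curie(o)
            elif local == "location":
                row["location"] = curie(o)
            elif local == "context":
                row["context"] = str(o)
            elif local == "evidence":
                row["evidence"] = curie(o)
            elif local == "isNegated":
                row["negated"] = str(o).lower() == "true"
            elif local == "source":
                row["source"] = str(o)
    if ignored:
        logger.info("kb N-Triples load: ignored %d unrecognized triple(s)", ignored)
    entities = [
        Entity(
            eid,
            row["name"],
            tuple(sorted(row["types"])),
            tuple(sorted(row["functions"])),
            tuple(sorted(row["same_as"])),
        )
        for eid, row in ent_rows.items()
    ]
    facts = [EventFact(id=fid, **row) for fid, row in fact_rows.items()]
    return entities, facts


# ---------------------------------------------------------------------------
# loading & validation
# ---------------------------------------------------------------------------


def _read_source(source: str | Path) -> str:
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        return Path(source).read_text()
    return str(source)


def load_kb(
    fact_source: str | Path,
    entity_source: str | Path | None,
    store: TermStore,
) -> KnowledgeBase:
    """Load, identity-resolve, validate and index a knowledge base.

    ``fact_source`` may be TSV or N-Triples (sniffed); N-Triples carries both
    entities and facts, in which case ``entity_source`` may be ``None``.
    Type/function/location/evidence CURIEs not present in ``store`` are
    auto-created as bare ontology roots (partial-excerpt policy).
    """
    fact_text = _read_source(fact_source)
    if fact_text.lstrip().startswith("<"):
        entities, facts = _kb_sources_from_ntriples(fact_text, store.prefix_map)
        if entity_source is not None:
            entities += entities_from_tsv(_read_source(entity_source))
    else:
        if entity_source is None:
            raise DataError("TSV fact source requires an entity source")
        entities = entities_from_tsv(_read_source(entity_source))
        facts = facts_from_tsv(fact_text)

    kb = KnowledgeBase()
    for entity in entities:
        kb.add_entity(entity)
    kb.resolve_identities()

    missing = [
        f.id
        for f in facts
        if kb.canonical(f.actor) not in kb.entities
        or kb.canonical(f.target) not in kb.entities
    ]
    if missing:
        raise DataError(
            "facts reference undeclared entities: " + ", ".join(sorted(missing))
        )
    for fact in sorted(facts, key=lambda f: f.id):
        kb.add_fact(fact)

    for entity in kb.entities.values():
        for curie in (*entity.types, *entity.functions):
            store.ensure(curie)
    for fact in kb.facts:
        if fact.location:
            store.ensure(fact.location)
        if fact.evidence:
            store.ensure(fact.evidence)
    return kb


def validate_kb(kb: KnowledgeBase) -> list[Diagnostic]:
    """Report (never raise) structural diagnostics for a knowledge base.

    Error level: dangling entity references, duplicate fact ids.  Info
    level: asserted/negated fact pairs identical in all fields but the
    negation flag — contradictions are representable by design and left to
    the scoring rules to penalize.
    """
    diagnostics: list[Diagnostic] = []
    seen_ids: set[str] = set()
    for fact in kb.facts:
        if fact.id in seen_ids:
            diagnostics.append(
                Diagnostic("error", "duplicate-fact-id", f"duplicate fact id {fact.id}")
            )
        seen_ids.add(fact.id)
        for role, curie in (("actor", fact.actor), ("target", fact.target)):
            if kb.canonical(curie) not in kb.entities:
                diagnostics.append(
                    Diagnostic(
                        "error",
                        "dangling-reference",
                        f"fact {fact.id}: {role} {curie} is not a declared entity",
                    )
                )
    by_body: dict[tuple, list[EventFact]] = {}
    for fact in kb.facts:
        body = (
            fact.event_type,
            fact.relation,
            fact.actor,
            fact.target,
            fact.location,
            fact.context,
        )
        by_body.setdefault(body, []).append(fact)
    for body, group in by_body.items():
        flags = {f.negated for f in group}
        if len(flags) == 2:
            ids = ", ".join(sorted(f.id for f in group))
            diagnostics.append(
                Diagnostic(
                    "info",
                    "contradiction-pair",
                    f"facts {ids} assert and negate the same event body",
                )
            )
    return diagnostics
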