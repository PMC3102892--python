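"""Subsumption-aware retrieval of event facts.

Two entry points:

* :func:`query_events` answers question-style patterns in which any field
  may be a wildcard and participants may be unbound variables ("which
  proteins bind the GAL1 promoter in wild type?"); bindings are returned
  per matching fact and deduplicated on the full binding tuple.
* :func:`candidates_for` retrieves the facts a hypothesized event is scored
  against.  Deliberately, only actor, target and perturbation context are
  filtered here: a fact with the wrong relation, location or negation flag
  is still a candidate — those deviations are *penalized by the scoring
  rules*, not excluded up front.  Context matching is exact-token, which is
  what makes an event hypothesized under an unobserved perturbation
  undecidable rather than merely low-scoring.

Type restrictions match by reflexive-transitive subsumption, so a pattern
asking for "RNA" participants also retrieves entities typed "messenger RNA".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SchemaError
from .hypothesis import EntityRef, HypothesizedEvent
from .kb import Entity, EventFact, KnowledgeBase
from .ontology import TermStore, expand_curie, normalize_curie

__all__ = [
    "EventPattern",
    "QueryRow",
    "QueryResult",
    "match_entity",
    "query_events",
    "candidates_for",
    "result_to_tsv",
]


@dataclass(frozen=True)
class EventPattern:
    """A question about single events; ``None`` fields are wildcards.

    ``evidence`` may be a CURIE (exact up to subsumption), a ``?variable``
    to bind per fact, or ``None``.
    """

    event_type: str | None = None
    relation: str | None = None
    actor: EntityRef | None = None
    target: EntityRef | None = None
    location: str | None = None
    context: str | None = None
    negated: bool | None = None
    evidence: str | None = None

    def __post_init__(self) -> None:
        if all(
            v is None
            for v in (
                self.event_type,
                self.relation,
                self.actor,
                self.target,
                self.location,
                self.context,
                self.negated,
                self.evidence,
            )
        ):
            raise SchemaError("event pattern must constrain at least one field")


@dataclass(frozen=True)
class QueryRow:
    bindings: tuple[tuple[str, str], ...]  # (variable, value) pairs, sorted
    fact_ids: tuple[str, ...]

    def as_dict(self) -> dict[str, str]:
        return dict(self.bindings)


@dataclass(frozen=True)
class QueryResult:
    rows: tuple[QueryRow, ...]

    def __len__(self) -> int:
        return len(self.rows)


def match_entity(
    ref: EntityRef,
    entity: Entity,
    store: TermStore,
    kb: KnowledgeBase | None = None,
) -> bool:
    """Does ``entity`` satisfy an entity reference?

    instance → canonical-id equality (aliases resolved through ``kb`` when
    given); type-restricted → some declared type of the entity is subsumed
    by the restriction; unbound → always true, unless the variable itself
    carries a type restriction.
    """
    if ref.mode == "instance":
        target = normalize_curie(ref.value)
        if kb is not None:
            target = kb.canonical(target)
        return entity.id == target
    if ref.mode in ("type", "unbound"):
        if ref.type_curie is None:
            return True
        restriction = store.resolve(ref.type_curie).id
        return any(store.is_a(t, restriction) for t in entity.types)
    raise SchemaError(f"unknown EntityRef mode {ref.mode!r}")


def _fact_matches(
    pattern: EventPattern, fact: EventFact, kb: KnowledgeBase, store: TermStore
) -> bool:
    if pattern.event_type is not None and fact.event_type != pattern.event_type:
        return False
    if pattern.relation is not None and fact.relation != pattern.relation:
        return False
    if pattern.context is not None and fact.context != pattern.context:
        return False
    if pattern.negated is not None and fact.negated != pattern.negated:
        return False
    if pattern.location is not None:
        if fact.location is None or not store.is_a(fact.location, pattern.location):
            return False
    if pattern.evidence is not None and not pattern.evidence.startswith("?"):
        want = normalize_curie(pattern.evidence)
        if fact.evidence is None:
            return False
        if fact.evidence in store and want in store:
            if not store.is_a(fact.evidence, want):
                return False
        elif fact.evidence != want:
            return False
    if pattern.actor is not None:
        if not match_entity(pattern.actor, kb.entity(fact.actor), store, kb):
            return False
    if pattern.target is not None:
        if not match_entity(pattern.target, kb.entity(fact.target), store, kb):
            return False
    return True


def _bindings(pattern: EventPattern, fact: EventFact) -> tuple[tuple[str, str], ...]:
    out: list[tuple[str, str]] = []
    if pattern.actor is not None and pattern.actor.mode == "unbound":
        out.append((pattern.actor.variable, fact.actor))
    if pattern.target is not None and pattern.target.mode == "unbound":
        out.append((pattern.target.variable, fact.target))
    if pattern.evidence is not None and pattern.evidence.startswith("?"):
        out.append((pattern.evidence, fact.evidence or ""))
    return tuple(sorted(out))


def query_events(
    pattern: EventPattern, kb: KnowledgeBase, store: TermStore
) -> QueryResult:
    """Return all facts matching every non-wildcard field of ``pattern``.

    Rows are deduplicated on the full binding tuple; each row lists the ids
    of every witnessing fact.  An empty result is a valid answer.
    """
    grouped: dict[tuple[tuple[str, str], ...], list[str]] = {}
    for fact in kb.facts:
        if _fact_matches(pattern, fact, kb, store):
            grouped.setdefault(_bindings(pattern, fact), []).append(fact.id)
    rows = tuple(
        QueryRow(bindings=binding, fact_ids=tuple(sorted(ids)))
        for binding, ids in sorted(grouped.items())
    )
    return QueryResult(rows=rows)


def candidates_for(
    event: HypothesizedEvent, kb: KnowledgeBase, store: TermStore
) -> list[EventFact]:
    """Facts eligible to support (or contradict) a hypothesized event.

    Filters on actor, target and exact perturbation context only; event
    type, relation, location and negation are left to the rules.  Unbound
    participant references are not allowed here.
    """
    for role, ref in (("actor", event.actor), ("target", event.target)):
        if ref.mode == "unbound":
            raise SchemaError(
                f"event {event.label!r}: {role} must be instance or "
                "type-restricted for scoring"
            )
    out = []
    for fact in kb.facts:
        if fact.context != event.context:
            continue
        if not match_entity(event.actor, kb.entity(fact.actor), store, kb):
            continue
        if not match_entity(event.target, kb.entity(fact.target), store, kb):
            continue
        out.append(fact)
    return sorted(out, key=lambda f: f.id)


def result_to_tsv(result: QueryResult, kb: KnowledgeBase, store: TermStore) -> str:
    """Export a result as TSV with Actor / Target / Perturbation Context /
    Evidence Type columns, one line per witnessing fact (actor and target
    as expanded IRIs, evidence as a CURIE or blank)."""
    pm = store.prefix_map
    lines = ["Actor\tTarget\tPerturbation Context\tEvidence Type"]
    seen: set[str] = set()
    fact_by_id = {f.id: f for f in kb.facts}
    for row in result.rows:
        for fid in row.fact_ids:
            if fid in seen:
                continue
            seen.add(fid)
            fact = fact_by_id[fid]
            lines.append(
                "\t".join(
                    (
                        expand_curie(fact.actor, pm),
                        expand_curie(fact.target, pm),
                        fact.context,
                        fact.evidence or "",
                    )
                )
            )
    return "\n".join(lines) + "\n"
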