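"""Hypotheses as trees of hypothesized events joined by AND / OR / XOR.

A hypothesis leaf states that a typed molecular event occurs (or, with
``negated_claim``, does not occur) between an actor and a target, optionally
at a location and under a genetic perturbation context.  Internal nodes
combine children with n-ary logical operators: AND (all events must hold;
scores add), OR (any event suffices; best score wins), XOR (exactly one
should hold).

The exchange format is a JSON document (see ``data/hypothesis.schema.json``
for the documented shape); an N-Triples serializer over the ``hq:``
vocabulary is provided for linked-data output parity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

import rdflib

from .errors import SchemaError, DataError
from .kb import EVENT_TYPES
from .ontology import expand_curie, normalize_curie

__all__ = [
    "EntityRef",
    "HypothesizedEvent",
    "HypothesisNode",
    "Hypothesis",
    "parse_hypothesis",
    "serialize_hypothesis",
]

OPERATORS = ("AND", "OR", "XOR")
_HQ = "http://example.org/hq/vocab#"
_HQD = "http://example.org/hq/data#"


@dataclass(frozen=True)
class EntityRef:
    """Reference to an event participant.

    Three modes: ``instance`` (a specific entity CURIE), ``type`` (any
    entity whose declared type is subsumed by ``type_curie``), and
    ``unbound`` (a query variable, optionally type-restricted).
    """

    mode: str
    value: str | None = None
    type_curie: str | None = None
    variable: str | None = None

    @classmethod
    def instance(cls, curie: str) -> "EntityRef":
        return cls("instance", value=normalize_curie(curie))

    @classmethod
    def type_restricted(cls, curie: str) -> "EntityRef":
        return cls("type", type_curie=normalize_curie(curie))

    @classmethod
    def unbound(cls, variable: str, type_curie: str | None = None) -> "EntityRef":
        if not variable.startswith("?"):
            variable = "?" + variable
        return cls(
            "unbound",
            variable=variable,
            type_curie=normalize_curie(type_curie) if type_curie else None,
        )

    def to_json(self) -> dict[str, str]:
        if self.mode == "instance":
            return {"instance": self.value}
        if self.mode == "type":
            return {"type": self.type_curie}
        doc: dict[str, str] = {"variable": self.variable}
        if self.type_curie:
            doc["type"] = self.type_curie
        return doc

    @classmethod
    def from_json(cls, doc: Any, where: str) -> "EntityRef":
        if not isinstance(doc, dict):
            raise SchemaError(f"{where}: entity reference must be an object")
        try:
            if "instance" in doc:
                return cls.instance(doc["instance"])
            if "variable" in doc:
                return cls.unbound(doc["variable"], doc.get("type"))
            if "type" in doc:
                return cls.type_restricted(doc["type"])
        except DataError as exc:
            raise SchemaError(f"{where}: {exc}") from exc
        raise SchemaError(
            f"{where}: entity reference needs 'instance', 'type' or 'variable'"
        )


@dataclass(frozen=True)
class HypothesizedEvent:
    label: str
    event_type: str
    relation: str
    actor: EntityRef
    target: EntityRef
    location: str | None = None
    context: str = "wt"
    negated_claim: bool = False

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise SchemaError(
                f"event {self.label!r}: unknown event_type {self.event_type!r}"
            )
        if self.location:
            object.__setattr__(self, "location", normalize_curie(self.location))
        if not self.context:
            object.__setattr__(self, "context", "wt")


@dataclass(frozen=True)
class HypothesisNode:
    """Either a leaf (``event`` set) or an operator with ≥2 children."""

    operator: str | None = None
    children: tuple["HypothesisNode", ...] = ()
    event: HypothesizedEvent | None = None

    @property
    def is_leaf(self) -> bool:
        return self.event is not None

    def __post_init__(self) -> None:
        if self.is_leaf:
            if self.operator is not None or self.children:
                raise SchemaError("a leaf node carries only an event")
        else:
            if self.operator not in OPERATORS:
                raise SchemaError(f"unknown operator {self.operator!r}")
            if len(self.children) < 2:
                raise SchemaError(
                    f"{self.operator} node needs at least 2 children, "
                    f"got {len(self.children)}"
                )

    def leaves(self) -> Iterator[HypothesizedEvent]:
        if self.is_leaf:
            yield self.event
        else:
            for child in self.children:
                yield from child.leaves()


@dataclass(frozen=True)
class Hypothesis:
    id: str
    title: str
    root: HypothesisNode

    def events(self) -> dict[str, HypothesizedEvent]:
        return {e.label: e for e in self.root.leaves()}


# ---------------------------------------------------------------------------
# document (JSON) dialect
# ---------------------------------------------------------------------------


def _event_from_json(doc: dict, counter: list[int], where: str) -> HypothesizedEvent:
    for key in ("event_type", "relation", "actor", "target"):
        if key not in doc:
            raise SchemaError(f"{where}: event missing required field {key!r}")
    label = doc.get("label")
    if not label:
        counter[0] += 1
        label = f"e{counter[0]}"
    return HypothesizedEvent(
        label=str(label),
        event_type=doc["event_type"],
        relation=str(doc["relation"]),
        actor=EntityRef.from_json(doc["actor"], f"{where}.actor"),
        target=EntityRef.from_json(doc["target"], f"{where}.target"),
        location=doc.get("location") or None,
        context=doc.get("context") or "wt",
        negated_claim=bool(doc.get("negated_claim", False)),
    )


def _node_from_json(doc: Any, counter: list[int], where: str) -> HypothesisNode:
    if not isinstance(doc, dict):
        raise SchemaError(f"{where}: node must be an object")
    if "event" in doc:
        return HypothesisNode(event=_event_from_json(doc["event"], counter, where))
    if "operator" in doc:
        children = doc.get("children", [])
        if not isinstance(children, list):
            raise SchemaError(f"{where}: children must be a list")
        return HypothesisNode(
            operator=str(doc["operator"]).upper(),
            children=tuple(
                _node_from_json(c, counter, f"{where}.children[{i}]")
                for i, c in enumerate(children)
            ),
        )
    raise SchemaError(f"{where}: node needs either 'event' or 'operator'")


def parse_hypothesis(doc: dict | str | Path) -> Hypothesis:
    """Parse a hypothesis document (dict, JSON text, or path to a file).

    Event labels absent from the document are assigned ``e1, e2, ...`` in
    document order; labels must be unique across the tree.
    """
    if isinstance(doc, Path) or (
        isinstance(doc, str) and "\n" not in doc and "{" not in doc and Path(doc).exists()
    ):
        doc = Path(doc).read_text()
    if isinstance(doc, str):
        try:
            doc = json.loads(doc)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"hypothesis document is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("hypothesis document must be a JSON object")
    if "root" not in doc:
        raise SchemaError("hypothesis document missing 'root'")
    counter = [0]
    root = _node_from_json(doc["root"], counter, "root")
    labels = [e.label for e in root.leaves()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise SchemaError(f"duplicate event labels: {', '.join(sorted(dupes))}")
    return Hypothesis(
        id=str(doc.get("id", "hypothesis-1")),
        title=str(doc.get("title", "")),
        root=root,
    )


def _event_to_json(event: HypothesizedEvent) -> dict:
    doc: dict[str, Any] = {
        "label": event.label,
        "event_type": event.event_type,
        "relation": event.relation,
        "actor": event.actor.to_json(),
        "target": event.target.to_json(),
    }
    if event.location:
        doc["location"] = event.location
    if event.context != "wt":
        doc["context"] = event.context
    if event.negated_claim:
        doc["negated_claim"] = True
    return doc


def _node_to_json(node: HypothesisNode) -> dict:
    if node.is_leaf:
        return {"event": _event_to_json(node.event)}
    return {
        "operator": node.operator,
        "children": [_node_to_json(c) for c in node.children],
    }


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _hypothesis_to_ntriples(h: Hypothesis, prefix_map: dict[str, str] | None) -> str:
    from .ontology import default_prefix_map

    pm = prefix_map or default_prefix_map()
    g = rdflib.Graph()
    hq = rdflib.Namespace(_HQ)
    hqd = rdflib.Namespace(_HQD)
    hyp = hqd[h.id]
    g.add((hyp, rdflib.RDF.type, hq.Hypothesis))
    if h.title:
        g.add((hyp, hq.title, rdflib.Literal(h.title)))

    op_counter = [0]

    def ref_triples(node: rdflib.URIRef, role: str, ref: EntityRef) -> None:
        if ref.mode == "instance":
            g.add((node, hq[role], rdflib.URIRef(expand_curie(ref.value, pm))))
        elif ref.mode == "type":
            g.add(
                (node, hq[role + "Type"], rdflib.URIRef(expand_curie(ref.type_curie, pm)))
            )
        else:
            g.add((node, hq[role + "Variable"], rdflib.Literal(ref.variable)))
            if ref.type_curie:
                g.add(
                    (
                        node,
                        hq[role + "Type"],
                        rdflib.URIRef(expand_curie(ref.type_curie, pm)),
                    )
                )

    def emit(node: HypothesisNode, parent: rdflib.URIRef) -> None:
        if node.is_leaf:
            e = node.event
            subj = hqd[f"{h.id}/{e.label}"]
            g.add((parent, hq.hasPart, subj))
            g.add((subj, rdflib.RDF.type, hq.Event))
            g.add((subj, hq.label, rdflib.Literal(e.label)))
            g.add((subj, hq.eventType, rdflib.Literal(e.event_type)))
            g.add((subj, hq.relation, rdflib.Literal(e.relation)))
            ref_triples(subj, "actor", e.actor)
            ref_triples(subj, "target", e.target)
            if e.location:
                g.add((subj, hq.location, rdflib.URIRef(expand_curie(e.location, pm))))
            g.add((subj, hq.context, rdflib.Literal(e.context)))
            g.add((subj, hq.negatedClaim, rdflib.Literal(e.negated_claim)))
        else:
            op_counter[0] += 1
            subj = hqd[f"{h.id}/op{op_counter[0]}"]
            g.add((parent, hq.hasPart, subj))
            group_class = {"AND": "AndGroup", "OR": "OrGroup", "XOR": "XorGroup"}
            g.add((subj, rdflib.RDF.type, hq[group_class[node.operator]]))
            for child in node.children:
                emit(child, subj)

    emit(h.root, hyp)
    return g.serialize(format="nt")


def serialize_hypothesis(
    h: Hypothesis,
    format: str = "document",
    prefix_map: dict[str, str] | None = None,
) -> str:
    """Serialize to the JSON ``document`` dialect or to ``ntriples``.

    The document form round-trips through :func:`parse_hypothesis` to an
    equal tree.
    """
    if format == "document":
        doc = {"id": h.id, "title": h.title, "root": _node_to_json(h.root)}
        return json.dumps(doc, indent=2) + "\n"
    if format == "ntriples":
        return _hypothesis_to_ntriples(h, prefix_map)
    raise SchemaError(f"unknown hypothesis serialization format {format!r}")
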