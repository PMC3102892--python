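"""Aggregate event scores through the hypothesis tree and emit the report.

Aggregation semantics (innermost operators first):

* **AND** — *combined event score*: the sum of child values; undecidable if
  any child is undecidable (a conjunction cannot be settled while one of
  its conjuncts has no data).
* **OR** — *maximum event score*: the maximum over decidable children;
  undecidable branches are skipped, and the OR is undecidable only when
  every branch is.
* **XOR** — *exclusive event score*: a child is "supported" iff decidable
  with value > 0; the XOR is undecidable if any child is undecidable,
  takes the supported child's value when exactly one child is supported,
  and 0 otherwise.  (The source semantics are stated as intent only —
  "only one of the events must be true" — so this deterministic reading is
  a documented design choice.)

The overall hypothesis score is the root aggregate's value, unnormalized:
conjunctions may exceed 1.  The report also carries an auxiliary per-event
mean, which would instead favour simpler hypotheses if used as the
headline score.

:func:`report_to_ntriples` renders the linked-data form: score instances
(``hq:HypothesisScore``, ``hq:CombinedEventScore``, ``hq:MaximumEventScore``,
``hq:ExclusiveEventScore``, ``hq:EventScore``, ``hq:RuleScore``) connected
to the hypothesis via *is-about* and *has-part* and to the supporting
facts via *is-about*, so the graph is navigable from data to hypothesis
and back.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from fractions import Fraction
from typing import Mapping

import rdflib

from .errors import SchemaError
from .hypothesis import Hypothesis, HypothesisNode
from .kb import KnowledgeBase
from .ontology import TermStore, expand_curie
from .scoring import EventScore, RuleSet, rulesets_digest, score_event

__all__ = [
    "AggregateScore",
    "EvaluationReport",
    "aggregate",
    "evaluate_hypothesis",
    "report_to_json",
    "report_to_ntriples",
    "report_overview_from_ntriples",
]

_HQ = "http://example.org/hq/vocab#"
_HQD = "http://example.org/hq/data#"

_KIND_BY_OP = {"AND": "combined", "OR": "maximum", "XOR": "exclusive"}
_CLASS_BY_KIND = {
    "event": "EventScore",
    "combined": "CombinedEventScore",
    "maximum": "MaximumEventScore",
    "exclusive": "ExclusiveEventScore",
}


@dataclass(frozen=True)
class AggregateScore:
    kind: str  # event | combined | maximum | exclusive
    status: str  # decidable | undecidable
    value: Fraction | None = None
    children: tuple["AggregateScore", ...] = ()
    event: EventScore | None = None

    @property
    def decidable(self) -> bool:
        return self.status == "decidable"


def aggregate(
    node: HypothesisNode, scores: Mapping[str, EventScore]
) -> AggregateScore:
    """Fold event scores up a hypothesis (sub)tree."""
    if node.is_leaf:
        try:
            es = scores[node.event.label]
        except KeyError:
            raise SchemaError(
                f"no score for event {node.event.label!r}"
            ) from None
        return AggregateScore(
            kind="event", status=es.status, value=es.normalized, event=es
        )
    children = tuple(aggregate(child, scores) for child in node.children)
    kind = _KIND_BY_OP[node.operator]
    if node.operator == "AND":
        if any(not c.decidable for c in children):
            return AggregateScore(kind=kind, status="undecidable", children=children)
        value = sum((c.value for c in children), Fraction(0))
    elif node.operator == "OR":
        decidable = [c for c in children if c.decidable]
        if not decidable:
            return AggregateScore(kind=kind, status="undecidable", children=children)
        value = max(c.value for c in decidable)
    else:  # XOR
        if any(not c.decidable for c in children):
            return AggregateScore(kind=kind, status="undecidable", children=children)
        supported = [c for c in children if c.value > 0]
        value = supported[0].value if len(supported) == 1 else Fraction(0)
    return AggregateScore(kind=kind, status="decidable", value=value, children=children)


@dataclass(frozen=True)
class EvaluationReport:
    hypothesis_id: str
    report_id: str
    overall: AggregateScore
    per_event: dict[str, EventScore]
    data_links: dict[str, str]
    ruleset_version: str
    timestamp: str
    mean_event_score: Fraction | None  # auxiliary; not the headline score

    @property
    def value(self) -> Fraction | None:
        return self.overall.value

    @property
    def status(self) -> str:
        return self.overall.status


def evaluate_hypothesis(
    h: Hypothesis,
    kb: KnowledgeBase,
    rulesets: Mapping[str, RuleSet],
    store: TermStore,
) -> EvaluationReport:
    """Score every leaf event, aggregate bottom-up, and link best facts.

    The report identifier is a deterministic hash of (hypothesis id, KB
    digest, rule-set digest), so regenerated reports are reproducible.
    """
    scores = {
        label: score_event(event, kb, rulesets, store)
        for label, event in h.events().items()
    }
    overall = aggregate(h.root, scores)
    data_links = {
        label: es.best_fact for label, es in scores.items() if es.best_fact
    }
    decidable = [es.normalized for es in scores.values() if es.decidable]
    mean = sum(decidable, Fraction(0)) / len(decidable) if decidable else None
    versions = {rs.version for rs in rulesets.values()}
    payload = f"{h.id}|{kb.digest()}|{rulesets_digest(rulesets)}".encode()
    return EvaluationReport(
        hypothesis_id=h.id,
        report_id="eval-" + hashlib.sha256(payload).hexdigest()[:16],
        overall=overall,
        per_event=scores,
        data_links=data_links,
        ruleset_version="+".join(sorted(versions)),
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        mean_event_score=mean,
    )


# ---------------------------------------------------------------------------
# JSON output
# ---------------------------------------------------------------------------


def _aggregate_to_json(agg: AggregateScore) -> dict:
    doc: dict = {"kind": agg.kind, "status": agg.status}
    if agg.value is not None:
        doc["value"] = float(agg.value)
    if agg.event is not None:
        doc["event"] = agg.event.event_label
    if agg.children:
        doc["children"] = [_aggregate_to_json(c) for c in agg.children]
    return doc


def _event_score_to_json(es: EventScore) -> dict:
    doc: dict = {"status": es.status}
    if es.decidable:
        doc.update(
            raw=es.raw,
            max_score=es.max_score,
            normalized=float(es.normalized),
            best_fact=es.best_fact,
            rule_scores=[
                {
                    "rule_id": rs.rule_id,
                    "points": rs.points,
                    "fired": rs.fired,
                    "about": rs.about,
                }
                for rs in es.rule_scores
            ],
        )
    return doc


def report_to_json(report: EvaluationReport) -> str:
    doc = {
        "hypothesis_id": report.hypothesis_id,
        "report_id": report.report_id,
        "ruleset_version": report.ruleset_version,
        "timestamp": report.timestamp,
        "overall_status": report.status,
        "overall_score": float(report.value) if report.value is not None else None,
        "mean_event_score_auxiliary": (
            float(report.mean_event_score)
            if report.mean_event_score is not None
            else None
        ),
        "overall": _aggregate_to_json(report.overall),
        "per_event": {
            label: _event_score_to_json(es)
            for label, es in sorted(report.per_event.items())
        },
        "data_links": dict(sorted(report.data_links.items())),
    }
    return json.dumps(doc, indent=2) + "\n"


# ---------------------------------------------------------------------------
# N-Triples output
# ---------------------------------------------------------------------------


def report_to_ntriples(
    report: EvaluationReport,
    store: TermStore | None = None,
) -> str:
    from .ontology import default_prefix_map

    pm = store.prefix_map if store is not None else default_prefix_map()
    g = rdflib.Graph()
    hq = rdflib.Namespace(_HQ)
    hqd = rdflib.Namespace(_HQD)

    eval_node = hqd[report.report_id]
    hyp_node = hqd[report.hypothesis_id]
    g.add((eval_node, rdflib.RDF.type, hq.EvaluationData))
    g.add((eval_node, hq.isAbout, hyp_node))
    g.add((eval_node, hq.rulesetVersion, rdflib.Literal(report.ruleset_version)))
    g.add((eval_node, hq.timestamp, rdflib.Literal(report.timestamp)))

    counter = [0]

    # the overall hypothesis score wraps the root aggregate, mirroring the
    # evaluation-data → hypothesis-score → partial-score chain
    overall_node = hqd[f"{report.report_id}/overall"]
    g.add((eval_node, hq.hasPart, overall_node))
    g.add((overall_node, rdflib.RDF.type, hq.HypothesisScore))
    g.add((overall_node, hq.status, rdflib.Literal(report.status)))
    if report.value is not None:
        g.add(
            (
                overall_node,
                hq.value,
                rdflib.Literal(float(report.value), datatype=rdflib.XSD.decimal),
            )
        )
    g.add((overall_node, hq.isAbout, hyp_node))

    def emit(agg: AggregateScore, parent: rdflib.URIRef, role: str) -> None:
        counter[0] += 1
        node = hqd[f"{report.report_id}/s{counter[0]}"]
        g.add((parent, hq[role], node))
        g.add((node, rdflib.RDF.type, hq[_CLASS_BY_KIND[agg.kind]]))
        g.add((node, hq.status, rdflib.Literal(agg.status)))
        if agg.value is not None:
            g.add(
                (
                    node,
                    hq.value,
                    rdflib.Literal(float(agg.value), datatype=rdflib.XSD.decimal),
                )
            )
        g.add((node, hq.isAbout, hyp_node))
        if agg.event is not None and agg.event.decidable:
            fact_uri = rdflib.URIRef(expand_curie(agg.event.best_fact, pm))
            g.add((node, hq.isAbout, fact_uri))
            for rs in agg.event.rule_scores:
                counter[0] += 1
                rnode = hqd[f"{report.report_id}/s{counter[0]}"]
                g.add((node, hq.hasPart, rnode))
                g.add((rnode, rdflib.RDF.type, hq.RuleScore))
                g.add((rnode, hq.rule, rdflib.Literal(rs.rule_id)))
                g.add(
                    (
                        rnode,
                        hq.value,
                        rdflib.Literal(rs.points, datatype=rdflib.XSD.integer),
                    )
                )
                g.add((rnode, hq.isAbout, fact_uri))
        for child in agg.children:
            emit(child, node, "hasPart")

    emit(report.overall, overall_node, "hasPart")
    return g.serialize(format="nt")


def report_overview_from_ntriples(text: str) -> tuple[str, float | None]:
    """Reload (status, overall value) from a serialized report graph."""
    g = rdflib.Graph()
    g.parse(data=text, format="nt")
    hq = rdflib.Namespace(_HQ)
    for node in g.subjects(rdflib.RDF.type, hq.HypothesisScore):
        status = str(g.value(node, hq.status))
        value = g.value(node, hq.value)
        return status, (float(value) if value is not None else None)
    raise SchemaError("no hypothesis-score node found in report graph")
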