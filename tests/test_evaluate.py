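"""Score aggregation through AND/OR/XOR and the linked evaluation report."""

import random
from fractions import Fraction

import pytest
import rdflib
from hypothesis import given, strategies as st

from hyeval.errors import SchemaError
from hyeval.evaluate import (
    aggregate,
    evaluate_hypothesis,
    report_overview_from_ntriples,
    report_to_json,
    report_to_ntriples,
)
from hyeval.hypothesis import EntityRef, HypothesisNode, HypothesizedEvent
from hyeval.scoring import EventScore

from .oracles import recur_value

HQ = "http://example.org/hq/vocab#"


def _leaf(label):
    return HypothesisNode(
        event=HypothesizedEvent(
            label=label,
            event_type="induction",
            relation="induce",
            actor=EntityRef.instance("sgd:Gal4p"),
            target=EntityRef.instance("sgd:GAL1"),
        )
    )


def _score(label, value):
    """Synthesize an EventScore with the given normalized value (or None)."""
    if value is None:
        return EventScore(event_label=label, status="undecidable")
    value = Fraction(value).limit_denominator(1000)
    return EventScore(
        event_label=label,
        status="decidable",
        raw=value.numerator,
        max_score=value.denominator,
        normalized=value,
        best_fact="hqd:f001",
    )


def _agg(operator, values):
    labels = [f"x{i}" for i in range(len(values))]
    node = HypothesisNode(operator=operator, children=tuple(_leaf(l) for l in labels))
    scores = {l: _score(l, v) for l, v in zip(labels, values)}
    return aggregate(node, scores)


def test_and_sums_child_scores():
    result = _agg("AND", ["0.8", "0.8"])
    assert result.kind == "combined"
    assert float(result.value) == 1.6


def test_and_with_undecidable_child_is_undecidable():
    result = _agg("AND", ["0.8", None, "0.8"])
    assert result.status == "undecidable" and result.value is None


def test_or_takes_maximum_over_decidable_branches():
    labels = ["a", "b", "c"]
    node = HypothesisNode(
        operator="OR",
        children=(
            _leaf("a"),
            HypothesisNode(operator="AND", children=(_leaf("b"), _leaf("c"))),
            HypothesisNode(operator="AND", children=(_leaf("d"), _leaf("e"))),
        ),
    )
    scores = {
        "a": _score("a", "0.8"),
        "b": _score("b", "0.8"),
        "c": _score("c", "0.8"),
        "d": _score("d", "0.8"),
        "e": _score("e", None),
    }
    result = aggregate(node, scores)
    assert result.status == "decidable"
    assert float(result.value) == 1.6  # the 0.8+0.8 branch wins; third skipped


def test_or_of_only_undecidable_children_is_undecidable():
    result = _agg("OR", [None, None])
    assert result.status == "undecidable"


def test_xor_with_exactly_one_supported_child_takes_its_score():
    result = _agg("XOR", ["0.8", "-0.2"])
    assert result.kind == "exclusive"
    assert float(result.value) == 0.8


def test_xor_with_two_supported_children_is_zero():
    assert _agg("XOR", ["0.8", "0.5"]).value == 0


def test_xor_with_undecidable_child_is_undecidable():
    assert _agg("XOR", ["0.8", None]).status == "undecidable"


def test_missing_leaf_score_is_an_error():
    node = HypothesisNode(operator="AND", children=(_leaf("p"), _leaf("q")))
    with pytest.raises(SchemaError, match="q"):
        aggregate(node, {"p": _score("p", "0.8")})


def test_and_or_xor_invariant_under_child_permutation():
    values = ["0.8", "-0.4", "0.3"]
    for op in ("AND", "OR", "XOR"):
        base = _agg(op, values)
        for perm in (["-0.4", "0.3", "0.8"], ["0.3", "0.8", "-0.4"]):
            other = _agg(op, perm)
            assert other.status == base.status
            assert other.value == base.value


def test_or_result_bounds_every_decidable_child():
    result = _agg("OR", ["0.4", None, "0.8", "-0.2"])
    for child in result.children:
        if child.decidable:
            assert result.value >= child.value


# -- worked end-to-end evaluations -------------------------------------------

def test_worked_hypothesis_scores_one_point_six(
    worked_hypothesis, gal_kb, gal_store, rulesets
):
    report = evaluate_hypothesis(worked_hypothesis, gal_kb, rulesets, gal_store)
    assert report.status == "decidable"
    assert float(report.value) == 1.6
    # the third branch (e4 AND e5 AND e6) is undecidable because of e5
    third = report.overall.children[2]
    assert third.kind == "combined" and third.status == "undecidable"
    assert report.per_event["e5"].status == "undecidable"
    # every decidable event links its best supporting fact
    for label, es in report.per_event.items():
        if es.decidable:
            assert report.data_links[label] == es.best_fact


def test_transport_hypothesis_scores_one(
    transport_hypothesis, gal_kb, gal_store, rulesets
):
    report = evaluate_hypothesis(transport_hypothesis, gal_kb, rulesets, gal_store)
    assert report.status == "decidable"
    assert float(report.value) == 1.0


def test_leaf_hypothesis_without_data_is_undecidable(gal_kb, gal_store, rulesets):
    from hyeval.hypothesis import parse_hypothesis

    h = parse_hypothesis(
        {
            "id": "no-data",
            "root": {
                "event": {
                    "event_type": "repression",
                    "relation": "repress",
                    "actor": {"instance": "sgd:Mig1p"},
                    "target": {"instance": "sgd:GAL7"},
                    "context": "galactose absent",
                }
            },
        }
    )
    report = evaluate_hypothesis(h, gal_kb, rulesets, gal_store)
    assert report.status == "undecidable" and report.value is None


def test_report_identifier_is_deterministic(
    transport_hypothesis, gal_kb, gal_store, rulesets
):
    r1 = evaluate_hypothesis(transport_hypothesis, gal_kb, rulesets, gal_store)
    r2 = evaluate_hypothesis(transport_hypothesis, gal_kb, rulesets, gal_store)
    assert r1.report_id == r2.report_id


def test_mean_event_score_is_auxiliary(worked_hypothesis, gal_kb, gal_store, rulesets):
    report = evaluate_hypothesis(worked_hypothesis, gal_kb, rulesets, gal_store)
    assert report.mean_event_score == Fraction(4, 5)  # five decidable 0.8 events
    assert "auxiliary" in report_to_json(report)


# -- linked-data report -------------------------------------------------------

def _count(graph, cls):
    return len(list(graph.subjects(rdflib.RDF.type, rdflib.URIRef(HQ + cls))))


def test_transport_report_graph_links_score_to_fact(
    transport_hypothesis, gal_kb, gal_store, rulesets
):
    report = evaluate_hypothesis(transport_hypothesis, gal_kb, rulesets, gal_store)
    g = rdflib.Graph()
    g.parse(data=report_to_ntriples(report, gal_store), format="nt")
    assert _count(g, "HypothesisScore") == 1
    assert _count(g, "EventScore") == 1
    overall = next(g.subjects(rdflib.RDF.type, rdflib.URIRef(HQ + "HypothesisScore")))
    assert float(g.value(overall, rdflib.URIRef(HQ + "value"))) == 1.0
    event_node = next(g.subjects(rdflib.RDF.type, rdflib.URIRef(HQ + "EventScore")))
    assert (overall, rdflib.URIRef(HQ + "hasPart"), event_node) in g
    # navigable score → supporting fact
    from hyeval.ontology import expand_curie

    fact_uri = rdflib.URIRef(expand_curie("hqd:f005", gal_store.prefix_map))
    assert (event_node, rdflib.URIRef(HQ + "isAbout"), fact_uri) in g


def test_undecidable_report_has_no_rule_scores(gal_kb, gal_store, rulesets):
    from hyeval.hypothesis import parse_hypothesis

    h = parse_hypothesis(
        {
            "id": "no-data",
            "root": {
                "event": {
                    "event_type": "inhibition",
                    "relation": "inhibit",
                    "actor": {"instance": "sgd:Gal80p"},
                    "target": {"instance": "sgd:Gal4p"},
                    "context": "GAL3 over-expressed",
                }
            },
        }
    )
    report = evaluate_hypothesis(h, gal_kb, rulesets, gal_store)
    g = rdflib.Graph()
    g.parse(data=report_to_ntriples(report, gal_store), format="nt")
    assert _count(g, "RuleScore") == 0
    status, value = report_overview_from_ntriples(report_to_ntriples(report, gal_store))
    assert status == "undecidable" and value is None


def test_worked_report_graph_operator_node_counts(
    worked_hypothesis, gal_kb, gal_store, rulesets
):
    """One maximum-score node (the OR) and two combined-score nodes (ANDs)."""
    report = evaluate_hypothesis(worked_hypothesis, gal_kb, rulesets, gal_store)
    g = rdflib.Graph()
    g.parse(data=report_to_ntriples(report, gal_store), format="nt")
    assert _count(g, "MaximumEventScore") == 1
    assert _count(g, "CombinedEventScore") == 2
    assert _count(g, "EventScore") == 6


def test_report_round_trips_status_and_value(
    worked_hypothesis, gal_kb, gal_store, rulesets
):
    report = evaluate_hypothesis(worked_hypothesis, gal_kb, rulesets, gal_store)
    nt = report_to_ntriples(report, gal_store)
    status, value = report_overview_from_ntriples(nt)
    assert status == report.status
    assert value == float(report.value)


# -- property: aggregation equals direct recursion ---------------------------

_values = st.one_of(
    st.none(),
    st.fractions(min_value=-2, max_value=2, max_denominator=10),
)


def _trees(depth):
    leaf = _values.map(lambda v: ("leaf", v))
    if depth == 0:
        return leaf
    return st.one_of(
        leaf,
        st.tuples(
            st.sampled_from(["AND", "OR", "XOR"]),
            st.lists(_trees(depth - 1), min_size=2, max_size=4),
        ),
    )


def _to_node_and_scores(tree, counter, scores):
    kind = tree[0]
    if kind == "leaf":
        counter[0] += 1
        label = f"n{counter[0]}"
        scores[label] = _score(label, tree[1])
        return _leaf(label)
    children = tuple(_to_node_and_scores(c, counter, scores) for c in tree[1])
    return HypothesisNode(operator=kind, children=children)


@given(tree=_trees(3))
def test_aggregation_matches_direct_recursion(tree):
    scores: dict[str, EventScore] = {}
    node = _to_node_and_scores(tree, [0], scores)
    result = aggregate(node, scores)
    expected = recur_value(tree)
    if expected is None:
        assert result.status == "undecidable" and result.value is None
    else:
        assert result.status == "decidable" and result.value == expected
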