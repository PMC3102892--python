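"""Per-event rule scoring: the published induce trace and its variations."""

import json
import random
from fractions import Fraction

import pytest

from hyeval.errors import SchemaError
from hyeval.fixtures import FixtureSpec, build_gal_fixture, gal_ontology, gen_random_kb
from hyeval.hypothesis import EntityRef, HypothesizedEvent
from hyeval.kb import Entity, EventFact, KnowledgeBase
from hyeval.scoring import (
    Rule,
    RuleSet,
    apply_rule,
    default_rulesets,
    load_rulesets,
    score_event,
)

from .oracles import brute_score

E1 = HypothesizedEvent(
    label="e1",
    event_type="induction",
    relation="induce",
    actor=EntityRef.instance("sgd:Gal4p"),
    target=EntityRef.instance("sgd:GAL1"),
    location="go:0005634",
)


def _induce_rules(rulesets):
    return rulesets["induction"]


def test_shipped_induce_ruleset_has_six_rules_max_five(rulesets):
    rs = _induce_rules(rulesets)
    assert len(rs.rules) == 6
    assert rs.max_score == 5
    assert not rs.reconstructed
    assert len(rulesets) == 7  # one per event type


def test_actor_type_rule_awards_point_for_protein(gal_kb, gal_store, rulesets):
    rule = _induce_rules(rulesets).rules[0]
    fact = gal_kb.facts[0]  # hqd:f001, actor Gal4p typed protein
    outcome = apply_rule(rule, E1, fact, gal_kb, gal_store)
    assert outcome.points == 1 and outcome.fired


def test_function_rule_scores_zero_without_annotation(gal_kb, gal_store, rulesets):
    """Gal4p lacks transcription factor activity: no point, no penalty."""
    rule = _induce_rules(rulesets).rules[2]
    fact = gal_kb.facts[0]
    outcome = apply_rule(rule, E1, fact, gal_kb, gal_store)
    assert outcome.points == 0 and not outcome.fired


def test_negation_rule_costs_two_points(gal_kb, gal_store, rulesets):
    from dataclasses import replace

    rule = _induce_rules(rulesets).rules[5]
    negated = replace(gal_kb.facts[0], negated=True)
    outcome = apply_rule(rule, E1, negated, gal_kb, gal_store)
    assert outcome.points == -2


def test_e1_scores_four_of_five(gal_kb, gal_store, rulesets):
    score = score_event(E1, gal_kb, rulesets, gal_store)
    assert score.status == "decidable"
    assert score.raw == 4
    assert score.max_score == 5
    assert float(score.normalized) == 0.8
    assert score.best_fact == "hqd:f001"
    assert [rs.points for rs in score.rule_scores] == [1, 1, 0, 1, 1, 0]


def test_event_without_context_data_is_undecidable(gal_kb, gal_store, rulesets):
    e5 = HypothesizedEvent(
        label="e5",
        event_type="inhibition",
        relation="inhibit",
        actor=EntityRef.instance("sgd:Gal80p"),
        target=EntityRef.instance("sgd:Gal4p"),
        context="GAL3 over-expressed",
    )
    score = score_event(e5, gal_kb, rulesets, gal_store)
    assert score.status == "undecidable"
    assert score.raw is None and score.normalized is None and score.best_fact is None


def _ideal_kb():
    """A KB whose single fact satisfies every positive induce condition."""
    kb = KnowledgeBase()
    kb.add_entity(Entity("sgd:TFp", types=("chebi:36080",), functions=("go:0003702",)))
    kb.add_entity(Entity("sgd:GENE", types=("so:0000236",)))
    return kb


def _ideal_fact(negated=False):
    return EventFact(
        id="hqd:ideal",
        event_type="induction",
        relation="induce",
        actor="sgd:TFp",
        target="sgd:GENE",
        location="go:0005634",
        negated=negated,
    )


def _ideal_event(negated_claim=False):
    return HypothesizedEvent(
        label="ex",
        event_type="induction",
        relation="induce",
        actor=EntityRef.instance("sgd:TFp"),
        target=EntityRef.instance("sgd:GENE"),
        negated_claim=negated_claim,
    )


def test_ideal_candidate_normalizes_to_exactly_one(gal_store, rulesets):
    kb = _ideal_kb()
    kb.add_fact(_ideal_fact())
    score = score_event(_ideal_event(), kb, rulesets, gal_store)
    assert score.raw == 5 and score.normalized == Fraction(1)


def test_negated_candidate_scores_two_fifths(gal_store, rulesets):
    """Rules 1,2,4,5 hold (+4), rule 3 does not apply here (0), negation −2."""
    kb = KnowledgeBase()
    kb.add_entity(Entity("sgd:Pp", types=("chebi:36080",)))
    kb.add_entity(Entity("sgd:GENE", types=("so:0000236",)))
    kb.add_fact(
        EventFact(
            id="hqd:neg",
            event_type="induction",
            relation="induce",
            actor="sgd:Pp",
            target="sgd:GENE",
            location="go:0005634",
            negated=True,
        )
    )
    event = HypothesizedEvent(
        label="ex",
        event_type="induction",
        relation="induce",
        actor=EntityRef.instance("sgd:Pp"),
        target=EntityRef.instance("sgd:GENE"),
    )
    score = score_event(event, kb, rulesets, gal_store)
    assert score.raw == 2
    assert float(score.normalized) == 0.4


def test_negated_claim_flips_negation_rule_polarity(gal_store, rulesets):
    """Hypothesizing a non-event: a negated fact confirms (+2), an
    asserted fact contradicts (−2); the denominator gains the bonus."""
    kb = _ideal_kb()
    kb.add_fact(_ideal_fact(negated=True))
    confirmed = score_event(_ideal_event(negated_claim=True), kb, rulesets, gal_store)
    assert confirmed.raw == 7 and confirmed.max_score == 7
    assert confirmed.normalized == Fraction(1)

    kb2 = _ideal_kb()
    kb2.add_fact(_ideal_fact(negated=False))
    contradicted = score_event(
        _ideal_event(negated_claim=True), kb2, rulesets, gal_store
    )
    assert contradicted.raw == 3  # 5 positive − 2 contradiction
    assert contradicted.normalized == Fraction(3, 7)


def test_missing_ruleset_is_schema_error(gal_kb, gal_store, rulesets):
    partial = {k: v for k, v in rulesets.items() if k != "induction"}
    with pytest.raises(SchemaError, match="induction"):
        score_event(E1, gal_kb, partial, gal_store)


def test_override_of_function_rule_changes_e1_to_three_fifths(gal_kb, gal_store):
    """Making rule 3 punitive (−1 when unmet) drops e1 from 0.8 to 0.6."""
    config = json.loads(
        __import__("importlib.resources", fromlist=["files"])
        .files("hyeval.data")
        .joinpath("default_rules.json")
        .read_text()
    )
    induce = next(b for b in config["rulesets"] if b["event_type"] == "induction")
    rule3 = next(r for r in induce["rules"] if r["id"] == "actor-function")
    rule3["points_if_false"] = -1
    rulesets = load_rulesets(config)
    score = score_event(E1, gal_kb, rulesets, gal_store)
    assert score.raw == 3
    assert float(score.normalized) == 0.6


def test_empty_rules_list_is_schema_error():
    with pytest.raises(SchemaError, match="empty"):
        load_rulesets({"rulesets": [{"event_type": "induction", "rules": []}]})


def test_unknown_condition_is_schema_error():
    with pytest.raises(SchemaError, match="frobnicates"):
        load_rulesets(
            {
                "rulesets": [
                    {
                        "event_type": "induction",
                        "rules": [
                            {
                                "id": "r1",
                                "condition": "frobnicates",
                                "points_if_true": 1,
                                "points_if_false": 0,
                            }
                        ],
                    }
                ]
            }
        )


def test_nonpositive_max_score_is_schema_error():
    with pytest.raises(SchemaError, match="positive"):
        RuleSet(
            event_type="induction",
            rules=(Rule("r1", "negated_in_kb", (), 0, -2),),
        )


def test_inverted_points_are_schema_error():
    with pytest.raises(SchemaError, match="≥"):
        Rule("r1", "relation_is", ("induce",), -1, 1)


# -- oracle equivalence and monotonicity ------------------------------------

def _random_events(rng, kb, n=25):
    facts = kb.facts
    for _ in range(n):
        fact = rng.choice(facts)
        actor = (
            EntityRef.instance(fact.actor)
            if rng.random() < 0.7
            else EntityRef.type_restricted(rng.choice(["chebi:36080", "chebi:24431"]))
        )
        target = (
            EntityRef.instance(fact.target)
            if rng.random() < 0.7
            else EntityRef.type_restricted(rng.choice(["so:0000110", "chebi:24431"]))
        )
        yield HypothesizedEvent(
            label="ex",
            event_type=rng.choice([fact.event_type, "induction", "transport"]),
            relation=fact.relation,
            actor=actor,
            target=target,
            context=rng.choice(["wt", "unseen-context"]),
            negated_claim=rng.random() < 0.2,
        )


@pytest.mark.parametrize("seed", [7, 23, 41])
def test_score_event_matches_brute_force_oracle(seed, rulesets):
    store = gal_ontology()
    kb = gen_random_kb(
        FixtureSpec(seed=seed, n_entities=15, n_facts=50,
                    negation_rate=0.25, annotation_completeness=0.6),
        store,
    )
    rng = random.Random(seed)
    for event in _random_events(rng, kb):
        score = score_event(event, kb, rulesets, store)
        status, raw, normalized, best = brute_score(
            event, kb, rulesets[event.event_type], store
        )
        assert score.status == status
        assert score.raw == raw
        assert score.normalized == normalized
        assert score.best_fact == best


@pytest.mark.parametrize("seed", [13, 37])
def test_adding_a_fact_never_decreases_event_scores(seed, rulesets):
    """Best-of-candidates monotonicity under KB growth."""
    store = gal_ontology()
    kb = gen_random_kb(
        FixtureSpec(seed=seed, n_entities=12, n_facts=30,
                    negation_rate=0.2, annotation_completeness=0.5),
        store,
    )
    rng = random.Random(seed + 100)
    events = list(_random_events(rng, kb, n=10))
    before = [score_event(e, kb, rulesets, store) for e in events]
    extra = rng.choice(kb.facts)
    kb.add_fact(
        EventFact(
            id="hqd:zzz-extra",
            event_type=extra.event_type,
            relation=extra.relation,
            actor=extra.actor,
            target=extra.target,
            location=extra.location,
            context=extra.context,
            negated=rng.random() < 0.5,
        )
    )
    after = [score_event(e, kb, rulesets, store) for e in events]
    for b, a in zip(before, after):
        if b.status == "decidable":
            assert a.status == "decidable"
            assert a.normalized >= b.normalized


@pytest.mark.parametrize("seed", [19])
def test_raw_score_bounded_by_max(seed, rulesets):
    store = gal_ontology()
    kb = gen_random_kb(
        FixtureSpec(seed=seed, n_entities=15, n_facts=60,
                    negation_rate=0.3, annotation_completeness=0.6),
        store,
    )
    rng = random.Random(seed)
    for event in _random_events(rng, kb, n=40):
        score = score_event(event, kb, rulesets, store)
        if score.status == "decidable":
            assert score.raw <= score.max_score
            lower = -sum(
                abs(r.points_if_false)
                for r in rulesets[event.event_type].rules
            )
            assert score.raw >= lower
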