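"""Rule-based scoring of a hypothesized event against candidate facts.

Each of the seven event types has an ordered rule set.  A rule checks one
condition of a candidate fact — participant types (by ontology
subsumption), an actor function annotation, the event location, the
relation verb, the negation flag, or the evidence code — and contributes
``points_if_true`` or ``points_if_false`` to the candidate's raw score.
Rules reward agreement with the "ideal" supporting fact and penalize
deviations; an explicit contradiction (the event negated in the knowledge
base) costs more than any other single deviation.

The event score is the best candidate's raw sum expressed as a *fraction
of the maximum achievable score*, which normalizes across event types with
differently sized rule sets.  The maximum counts only positive
contributions, with the negation rule contributing zero at best.  If no
candidate exists for the event's actor/target/context, the event is
**undecidable**: no raw score, no normalized score, no supporting fact.

The shipped gene-induction rule set (see ``data/default_rules.json``):

1. actor typed protein (chebi:36080) or RNA (chebi:33697): +1 / −1
2. target typed gene (so:0000236): +1 / −1
3. actor annotated with transcription factor activity (go:0003702): +1 / 0
4. event located in the nucleus (go:0005634): +1 / −1
5. relation is "induce": +1 / −1
6. event negated in the knowledge base: −2 (0 otherwise)

maximum 5 points.  The other six rule sets follow the same template with
event-appropriate arguments and are marked ``"reconstructed": true`` in
the config; all are overridable via :func:`load_rulesets`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Mapping

from .errors import DataError, SchemaError
from .hypothesis import HypothesizedEvent
from .kb import EVENT_TYPES, EventFact, KnowledgeBase
from .ontology import TermStore, normalize_curie
from .query import candidates_for

__all__ = [
    "CONDITIONS",
    "Rule",
    "RuleSet",
    "RuleScore",
    "EventScore",
    "apply_rule",
    "score_event",
    "load_rulesets",
    "default_rulesets",
    "rulesets_digest",
]

CONDITIONS = (
    "actor_is_a",
    "target_is_a",
    "actor_has_function",
    "location_is",
    "relation_is",
    "negated_in_kb",
    "evidence_is",
)


@dataclass(frozen=True)
class Rule:
    """One scored condition.

    For ``negated_in_kb`` the condition is *satisfied* when the fact's
    negation flag agrees with the claim's polarity, so the default
    (0, −2) pair yields 0 for consistent facts and −2 for contradictions.
    """

    id: str
    condition: str
    args: tuple[str, ...]
    points_if_true: int
    points_if_false: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise SchemaError(
                f"rule {self.id!r}: unknown condition {self.condition!r}"
            )
        if self.points_if_true < self.points_if_false:
            raise SchemaError(
                f"rule {self.id!r}: points_if_true must be ≥ points_if_false"
            )
        if self.condition != "relation_is":
            object.__setattr__(
                self, "args", tuple(normalize_curie(a) for a in self.args)
            )


@dataclass(frozen=True)
class RuleSet:
    event_type: str
    rules: tuple[Rule, ...]
    version: str = "default"
    reconstructed: bool = False

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise SchemaError(f"rule set for unknown event type {self.event_type!r}")
        if not self.rules:
            raise SchemaError(f"rule set {self.event_type!r}: empty rules list")
        if self.max_score <= 0:
            raise SchemaError(
                f"rule set {self.event_type!r}: max_score must be positive"
            )

    @property
    def max_score(self) -> int:
        """Sum of best-case positive contributions (negation rule: 0)."""
        total = 0
        for rule in self.rules:
            if rule.condition == "negated_in_kb":
                continue
            total += max(rule.points_if_true, 0)
        return total

    def max_score_for(self, negated_claim: bool) -> int:
        """Best achievable raw score for a claim of the given polarity.

        For a hypothesized *non*-event the negation rule flips polarity and
        a confirming negated fact earns a bonus, which must enter the
        denominator to keep fraction-of-maximum semantics.
        """
        if not negated_claim:
            return self.max_score
        total = self.max_score
        for rule in self.rules:
            if rule.condition == "negated_in_kb":
                total += max(-rule.points_if_false, 0)
        return total


@dataclass(frozen=True)
class RuleScore:
    rule_id: str
    points: int
    fired: bool
    about: str | None = None  # fact id the rule was executed on


@dataclass(frozen=True)
class EventScore:
    """Outcome of scoring one hypothesized event.

    ``status == "undecidable"`` ⇔ ``raw``, ``normalized`` and ``best_fact``
    are all absent.  ``normalized`` is an exact rational.
    """

    event_label: str
    status: str
    raw: int | None = None
    max_score: int | None = None
    normalized: Fraction | None = None
    best_fact: str | None = None
    rule_scores: tuple[RuleScore, ...] = ()

    @property
    def decidable(self) -> bool:
        return self.status == "decidable"


def _condition_holds(
    rule: Rule,
    event: HypothesizedEvent,
    fact: EventFact,
    kb: KnowledgeBase,
    store: TermStore,
) -> bool:
    if rule.condition == "actor_is_a":
        entity = kb.entity(fact.actor)
        return any(store.is_a(t, a) for t in entity.types for a in rule.args)
    if rule.condition == "target_is_a":
        entity = kb.entity(fact.target)
        return any(store.is_a(t, a) for t in entity.types for a in rule.args)
    if rule.condition == "actor_has_function":
        entity = kb.entity(fact.actor)
        return any(store.is_a(f, a) for f in entity.functions for a in rule.args)
    if rule.condition == "location_is":
        if fact.location is None:
            return False
        return any(store.is_a(fact.location, a) for a in rule.args)
    if rule.condition == "relation_is":
        return fact.relation in rule.args
    if rule.condition == "evidence_is":
        if fact.evidence is None:
            return False
        return any(store.is_a(fact.evidence, a) for a in rule.args)
    if rule.condition == "negated_in_kb":
        return fact.negated == event.negated_claim
    raise SchemaError(f"unknown condition {rule.condition!r}")  # pragma: no cover


def apply_rule(
    rule: Rule,
    event: HypothesizedEvent,
    fact: EventFact,
    kb: KnowledgeBase,
    store: TermStore,
) -> RuleScore:
    """Evaluate one rule on one candidate fact.

    Condition arguments must resolve in the term store (they are resolved
    through subsumption); a hypothesized non-event flips the negation
    rule's polarity so that a negated fact confirms rather than refutes.
    """
    if rule.condition not in ("relation_is", "negated_in_kb"):
        for arg in rule.args:
            store.resolve(arg)  # raises DataError naming the CURIE
    fired = _condition_holds(rule, event, fact, kb, store)
    if rule.condition == "negated_in_kb" and event.negated_claim:
        points = -rule.points_if_false if fired else rule.points_if_false
    else:
        points = rule.points_if_true if fired else rule.points_if_false
    return RuleScore(rule_id=rule.id, points=points, fired=fired, about=fact.id)


def score_event(
    event: HypothesizedEvent,
    kb: KnowledgeBase,
    rulesets: Mapping[str, RuleSet],
    store: TermStore,
) -> EventScore:
    """Score ``event`` against every candidate fact; keep the best.

    Candidates are retrieved by actor/target/context; each is scored by
    every rule of the event type's rule set; the candidate with the
    maximal raw sum wins (ties break to the lexicographically smallest
    fact id).  No candidates → undecidable.
    """
    try:
        ruleset = rulesets[event.event_type]
    except KeyError:
        raise SchemaError(
            f"no rule set for event type {event.event_type!r}"
        ) from None
    candidates = candidates_for(event, kb, store)
    if not candidates:
        return EventScore(event_label=event.label, status="undecidable")
    best: tuple[int, str] | None = None
    best_scores: tuple[RuleScore, ...] = ()
    for fact in candidates:  # already sorted by id; strict > keeps smallest
        scores = tuple(
            apply_rule(rule, event, fact, kb, store) for rule in ruleset.rules
        )
        raw = sum(s.points for s in scores)
        if best is None or raw > best[0]:
            best = (raw, fact.id)
            best_scores = scores
    raw, fact_id = best
    max_score = ruleset.max_score_for(event.negated_claim)
    return EventScore(
        event_label=event.label,
        status="decidable",
        raw=raw,
        max_score=max_score,
        normalized=Fraction(raw, max_score),
        best_fact=fact_id,
        rule_scores=best_scores,
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def load_rulesets(config: dict | str | Path) -> dict[str, RuleSet]:
    """Load a rule-set configuration (dict, JSON text, or file path)."""
    if isinstance(config, Path) or (
        isinstance(config, str) and "{" not in config
    ):
        path = Path(config)
        if not path.exists():
            raise SchemaError(f"rule-set config not found: {path}")
        config = path.read_text()
    if isinstance(config, str):
        try:
            config = json.loads(config)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"rule-set config is not valid JSON: {exc}") from exc
    if not isinstance(config, dict) or "rulesets" not in config:
        raise SchemaError("rule-set config must be an object with 'rulesets'")
    version = str(config.get("version", "custom"))
    out: dict[str, RuleSet] = {}
    for block in config["rulesets"]:
        rules = tuple(
            Rule(
                id=str(r.get("id", f"rule{i + 1}")),
                condition=r.get("condition", ""),
                args=tuple(r.get("args", [])),
                points_if_true=int(r.get("points_if_true", 0)),
                points_if_false=int(r.get("points_if_false", 0)),
            )
            for i, r in enumerate(block.get("rules", []))
        )
        ruleset = RuleSet(
            event_type=block.get("event_type", ""),
            rules=rules,
            version=version,
            reconstructed=bool(block.get("reconstructed", False)),
        )
        if ruleset.event_type in out:
            raise SchemaError(f"duplicate rule set for {ruleset.event_type!r}")
        out[ruleset.event_type] = ruleset
    return out


def default_rulesets() -> dict[str, RuleSet]:
    """The shipped configuration covering all seven event types."""
    text = resources.files("hyeval.data").joinpath("default_rules.json").read_text()
    return load_rulesets(json.loads(text))


def rulesets_digest(rulesets: Mapping[str, RuleSet]) -> str:
    """Stable content hash of a rule-set mapping (for report identifiers)."""
    payload = json.dumps(
        {
            et: [
                (r.id, r.condition, list(r.args), r.points_if_true, r.points_if_false)
                for r in rs.rules
            ]
            for et, rs in sorted(rulesets.items())
        },
        sort_keys=True,
    ).encode()
    return hashlib.sha256(payload).hexdigest()
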