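"""Independent brute-force oracles used to cross-check the implementation.

Everything here re-derives its answers from raw data (term parent lists,
fact field tuples) with the simplest possible algorithms — breadth-first
reachability, exhaustive scans, direct recursion — and shares no logic
with the package's own matchers and scorers.
"""

from collections import deque
from fractions import Fraction


def bfs_is_a(term, ancestor, parents):
    """Reflexive-transitive reachability over a {child: [parents]} dict."""
    queue = deque([term])
    seen = set()
    while queue:
        cur = queue.popleft()
        if cur == ancestor:
            return True
        if cur in seen:
            continue
        seen.add(cur)
        queue.extend(parents.get(cur, []))
    return False


def parent_dict(store):
    return {tid: list(t.parents) for tid, t in store.terms.items()}


def _ref_matches(ref, entity_id, kb, parents):
    entity = kb.entities[kb.aliases.get(entity_id, entity_id)]
    if ref.mode == "instance":
        return entity.id == kb.aliases.get(ref.value, ref.value)
    if ref.type_curie is None:
        return True
    return any(bfs_is_a(t, ref.type_curie, parents) for t in entity.types)


def brute_query(pattern, kb, store):
    """Exhaustive scan; returns the set of (bindings, fact_id) pairs."""
    parents = parent_dict(store)
    hits = []
    for fact in kb.facts:
        if pattern.event_type is not None and fact.event_type != pattern.event_type:
            continue
        if pattern.relation is not None and fact.relation != pattern.relation:
            continue
        if pattern.context is not None and fact.context != pattern.context:
            continue
        if pattern.negated is not None and fact.negated != pattern.negated:
            continue
        if pattern.location is not None:
            if fact.location is None or not bfs_is_a(
                fact.location, pattern.location, parents
            ):
                continue
        if pattern.evidence is not None and not pattern.evidence.startswith("?"):
            if fact.evidence is None or not bfs_is_a(
                fact.evidence, pattern.evidence, parents
            ):
                continue
        if pattern.actor is not None and not _ref_matches(
            pattern.actor, fact.actor, kb, parents
        ):
            continue
        if pattern.target is not None and not _ref_matches(
            pattern.target, fact.target, kb, parents
        ):
            continue
        bindings = []
        if pattern.actor is not None and pattern.actor.mode == "unbound":
            bindings.append((pattern.actor.variable, fact.actor))
        if pattern.target is not None and pattern.target.mode == "unbound":
            bindings.append((pattern.target.variable, fact.target))
        if pattern.evidence is not None and pattern.evidence.startswith("?"):
            bindings.append((pattern.evidence, fact.evidence or ""))
        hits.append((tuple(sorted(bindings)), fact.id))
    return set(hits)


def _rule_points(rule, event, fact, kb, parents):
    cond = rule.condition
    if cond == "actor_is_a":
        entity = kb.entities[fact.actor]
        holds = any(
            bfs_is_a(t, a, parents) for t in entity.types for a in rule.args
        )
    elif cond == "target_is_a":
        entity = kb.entities[fact.target]
        holds = any(
            bfs_is_a(t, a, parents) for t in entity.types for a in rule.args
        )
    elif cond == "actor_has_function":
        entity = kb.entities[fact.actor]
        holds = any(
            bfs_is_a(f, a, parents) for f in entity.functions for a in rule.args
        )
    elif cond == "location_is":
        holds = fact.location is not None and any(
            bfs_is_a(fact.location, a, parents) for a in rule.args
        )
    elif cond == "relation_is":
        holds = fact.relation in rule.args
    elif cond == "evidence_is":
        holds = fact.evidence is not None and any(
            bfs_is_a(fact.evidence, a, parents) for a in rule.args
        )
    elif cond == "negated_in_kb":
        holds = fact.negated == event.negated_claim
        if event.negated_claim:
            return -rule.points_if_false if holds else rule.points_if_false
    else:  # pragma: no cover
        raise AssertionError(cond)
    return rule.points_if_true if holds else rule.points_if_false


def brute_score(event, kb, ruleset, store):
    """(status, raw, normalized, best_fact) by exhaustive enumeration."""
    parents = parent_dict(store)
    candidates = [
        f
        for f in kb.facts
        if f.context == event.context
        and _ref_matches(event.actor, f.actor, kb, parents)
        and _ref_matches(event.target, f.target, kb, parents)
    ]
    if not candidates:
        return ("undecidable", None, None, None)
    scored = sorted(
        (
            (-sum(_rule_points(r, event, f, kb, parents) for r in ruleset.rules), f.id)
            for f in candidates
        )
    )
    raw = -scored[0][0]
    best_id = scored[0][1]
    max_score = sum(
        max(r.points_if_true, 0)
        for r in ruleset.rules
        if r.condition != "negated_in_kb"
    )
    if event.negated_claim:
        max_score += sum(
            max(-r.points_if_false, 0)
            for r in ruleset.rules
            if r.condition == "negated_in_kb"
        )
    return ("decidable", raw, Fraction(raw, max_score), best_id)


def recur_value(tree):
    """Direct recursion over ('leaf', value|None) / (op, [children]) tuples.

    Returns a Fraction for a decidable node or None for undecidable.
    """
    kind = tree[0]
    if kind == "leaf":
        return tree[1]
    values = [recur_value(c) for c in tree[1]]
    if kind == "AND":
        if any(v is None for v in values):
            return None
        return sum(values, Fraction(0))
    if kind == "OR":
        decidable = [v for v in values if v is not None]
        return max(decidable) if decidable else None
    if kind == "XOR":
        if any(v is None for v in values):
            return None
        positive = [v for v in values if v > 0]
        return positive[0] if len(positive) == 1 else Fraction(0)
    raise AssertionError(kind)  # pragma: no cover
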