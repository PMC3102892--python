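{
  "version": "default-1",
  "comment": "Default rule sets for the seven event types. The 'induction' set is the published one; the other six are RECONSTRUCTED from the same template (actor type, target type, actor function, location, relation, negation) with event-appropriate arguments, and are fully overridable.",
  "rulesets": [
    {
      "event_type": "induction",
      "reconstructed": false,
      "rules": [
        {"id": "actor-type", "condition": "actor_is_a", "args": ["chebi:36080", "chebi:33697"], "points_if_true": 1, "points_if_false": -1},
        {"id": "target-type", "condition": "target_is_a", "args": ["so:0000236"], "points_if_true": 1, "points_if_false": -1},
        {"id": "actor-function", "condition": "actor_has_function", "args": ["go:0003702"], "points_if_true": 1, "points_if_false": 0},
        {"id": "location", "condition": "location_is", "args": ["go:0005634"], "points_if_true": 1, "points_if_false": -1},
        {"id": "relation", "condition": "relation_is", "args": ["induce"], "points_if_true": 1, "points_if_false": -1},
        {"id": "not-negated", "condition": "negated_in_kb", "args": [], "points_if_true": 0, "points_if_false": -2}
      ]
    },
    {
      "event_type": "repression",
      "reconstructed": true,
      "rules": [
        {"id": "actor-type", "condition": "actor_is_a", "args": ["chebi:36080", "chebi:33697"], "points_if_true": 1, "points_if_false": -1},
        {"id": "target-type", "condition": "target_is_a", "args": ["so:0000236"], "points_if_true": 1, "points_if_false": -1},
        {"id": "actor-function", "condition": "actor_has_function", "args": ["go:0003702"], "points_if_true": 1, "points_if_false": 0},
        {"id": "location", "condition": "location_is", "args": ["go:0005634"], "points_if_true": 1, "points_if_false": -1},
        {"id": "relation", "condition": "relation_is", "args": ["repress"], "points_if_true": 1, "points_if_false": -1},
        {"id": "not-negated", "condition": "negated_in_kb", "args": [], "points_if_true": 0, "points_if_false": -2}
      ]
    },
    {
      "event_type": "transport",
      "reconstructed": true,
      "rules": [
        {"id": "actor-type", "condition": "actor_is_a", "args": ["chebi:36080"], "points_if_true": 1, "points_if_false": -1},
        {"id": "target-type", "condition": "target_is_a", "args": ["chebi:24431"], "points_if_true": 1, "points_if_false": -1},
        {"id": "actor-function", "condition": "actor_has_function", "args": ["go:0005215"], "points_if_true": 1, "points_if_false": 0},
        {"id": "location", "condition": "location_is", "args": ["go:0016020"], "points_if_true": 1, "points_if_false": -1},
        {"id": "relation", "condition": "relation_is", "args": ["transport"], "points_if_true": 1, "points_if_false": -1},
        {"id": "not-negated", "condition": "negated_in_kb", "args": [], "points_if_true": 0, "points_if_false": -2}
      ]
    },
    {
      "event_type": "activation",
      "reconstructed": true,
      "rules": [
        {"id": "actor-type", "condition": "actor_is_a", "args": ["chebi:36080", "chebi:33697"], "points_if_true": 1, "points_if_false": -1},
        {"id": "target-type", "condition": "target_is_a", "args": ["chebi:36080"], "points_if_true": 1, "points_if_false": -1},
        {"id": "actor-function", "condition": "actor_has_function", "args": ["go:0005515"], "points_if_true": 1, "points_if_false": 0},
        {"id": "location", "condition": "location_is", "args": ["go:0005737"], "points_if_true": 1, "points_if_false": -1},
        {"id": "relation", "condition": "relation_is", "args": ["activate"], "points_if_true": 1, "points_if_false": -1},
        {"id": "not-negated", "condition": "negated_in_kb", "args": [], "points_if_true": 0, "points_if_false": -2}
      ]
    },
    {
      "event_type": "inhibition",
      "reconstructed": true,
      "rules": [
        {"id": "actor-type", "condition": "actor_is_a", "args": ["chebi:36080", "chebi:33697"], "points_if_true": 1, "points_if_false": -1},
        {"id": "target-type", "condition": "target_is_a", "args": ["chebi:36080"], "points_if_true": 1, "points_if_false": -1},
        {"id": "actor-function", "condition": "actor_has_function", "args": ["go:0004857"], "points_if_true": 1, "points_if_false": 0},
        {"id": "location", "condition": "location_is", "args": ["go:0005737"], "points_if_true": 1, "points_if_false": -1},
        {"id": "relation", "condition": "relation_is", "args": ["inhibit"], "points_if_true": 1, "points_if_false": -1},
        {"id": "not-negated", "condition": "negated_in_kb", "args": [], "points_if_true": 0, "points_if_false": -2}
      ]
    },
    {
      "event_type": "protein-protein-binding",
      "reconstructed": true,
      "rules": [
        {"id": "actor-type", "condition": "actor_is_a", "args": ["chebi:36080"], "points_if_true": 1, "points_if_false": -1},
        {"id": "target-type", "condition": "target_is_a", "args": ["chebi:36080"], "points_if_true": 1, "points_if_false": -1},
        {"id": "actor-function", "condition": "actor_has_function", "args": ["go:0005515"], "points_if_true": 1, "points_if_false": 0},
        {"id": "location", "condition": "location_is", "args": ["go:0005737"], "points_if_true": 1, "points_if_false": -1},
        {"id": "relation", "condition": "relation_is", "args": ["bind"], "points_if_true": 1, "points_if_false": -1},
        {"id": "not-negated", "condition": "negated_in_kb", "args": [], "points_if_true": 0, "points_if_false": -2}
      ]
    },
    {
      "event_type": "protein-nucleic-acid-binding",
      "reconstructed": true,
      "rules": [
        {"id": "actor-type", "condition": "actor_is_a", "args": ["chebi:36080"], "points_if_true": 1, "points_if_false": -1},
        {"id": "target-type", "condition": "target_is_a", "args": ["so:0000110"], "points_if_true": 1, "points_if_false": -1},
        {"id": "actor-function", "condition": "actor_has_function", "args": ["go:0003677"], "points_if_true": 1, "points_if_false": 0},
        {"id": "location", "condition": "location_is", "args": ["go:0005634"], "points_if_true": 1, "points_if_false": -1},
        {"id": "relation", "condition": "relation_is", "args": ["bind"], "points_if_true": 1, "points_if_false": -1},
        {"id": "not-negated", "condition": "negated_in_kb", "args": [], "points_if_true": 0, "points_if_false": -2}
      ]
    }
  ]
}
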