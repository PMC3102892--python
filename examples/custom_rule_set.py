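"""Override a scoring rule and observe the effect on an event score.

The shipped induce rule set gives the actor-function rule an asymmetric
(+1 / 0) payoff: a missing transcription-factor-activity annotation costs
nothing.  Making it punitive (-1) drops the Gal4p→GAL1 event from 4/5 to
3/5.  Rule sets are plain JSON, so alternative scoring schemes are a
config edit, not a code change.
"""

import json
from importlib import resources

from hyeval.fixtures import build_gal_fixture, gal_regulation_hypothesis
from hyeval.scoring import default_rulesets, load_rulesets, score_event

kb, store = build_gal_fixture()
e1 = gal_regulation_hypothesis().events()["e1"]

baseline = score_event(e1, kb, default_rulesets(), store)
print(f"baseline:  {baseline.raw}/{baseline.max_score} → {float(baseline.normalized):g}")

config = json.loads(
    resources.files("hyeval.data").joinpath("default_rules.json").read_text()
)
induce = next(b for b in config["rulesets"] if b["event_type"] == "induction")
next(r for r in induce["rules"] if r["id"] == "actor-function")["points_if_false"] = -1

modified = score_event(e1, kb, load_rulesets(config), store)
print(f"punitive:  {modified.raw}/{modified.max_score} → {float(modified.normalized):g}")

# The normalized score falls from 0.8 to 0.6: under the stricter rule,
# Gal4p's missing function annotation now counts against the hypothesis.
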