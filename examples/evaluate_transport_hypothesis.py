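"""Score the galactose-transport hypothesis and emit the linked report.

Gal2p transporting galactose across the plasma membrane is fully
supported: the matching fact satisfies every positive condition of the
transport rule set, so fraction-of-maximum normalization yields exactly 1.
The N-Triples report links scores to the hypothesis (is-about/has-part)
and to the supporting fact, navigable in both directions.
"""

from hyeval.evaluate import evaluate_hypothesis, report_to_ntriples
from hyeval.fixtures import build_gal_fixture, galactose_transport_hypothesis
from hyeval.scoring import default_rulesets

kb, store = build_gal_fixture()
report = evaluate_hypothesis(
    galactose_transport_hypothesis(), kb, default_rulesets(), store
)

print(f"overall: {report.status}, score {float(report.value):g}")
print(f"supporting fact: {report.data_links['e1']}")
print()
print("linked-data report (first lines):")
for line in report_to_ntriples(report, store).splitlines()[:6]:
    print(" ", line)

# Score 1 means maximal support: every rule of the transport set rewarded
# the best candidate fact and nothing contradicted the claim.
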