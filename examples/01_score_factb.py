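"""Score a FACT-B questionnaire from item-level responses.

Builds one synthetic respondent (37 items answered 0-4, one physical-
wellbeing item left blank), scores it with the default item configuration,
and prints the five subscale totals.  Negatively worded items are
reverse-scored (4 - value) and the missing item is prorated from the rest
of its subscale, the standard FACIT convention.
"""

import numpy as np

from utilmap import FactBResponse, load_item_config, score_factb

rng = np.random.default_rng(0)
config = load_item_config().sort_values("item")

# a moderately impaired respondent: contributions around 2-3 of 4
values = [int(v) for v in rng.integers(1, 4, 37)]
values[2] = None  # third PWB item unanswered

response = FactBResponse.from_items(values, config)
scores = score_factb(response, prorate=True)

print(f"PWB   {scores.pwb:6.2f} / 28")
print(f"SWB   {scores.swb:6.2f} / 28")
print(f"EWB   {scores.ewb:6.2f} / 24")
print(f"FWB   {scores.fwb:6.2f} / 28")
print(f"BCS   {scores.bcs:6.2f} / 40")
print(f"total {scores.total:6.2f} / 148   (higher = better quality of life)")
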