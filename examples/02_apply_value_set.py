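"""Convert EQ-5D-5L profiles to utilities through a value set.

Value sets (tariffs) are country-specific and supplied as data, never code.
This example builds a small SYNTHETIC additive value set — per-dimension,
per-level decrements subtracted from 1, the shape of most published EQ-5D-5L
tariffs; the decrements are illustrative, not any country's real weights —
and converts a few profiles.  Level 1 means "no problems"; the all-ones
profile is full health and maps to exactly 1.
"""

from utilmap import Eq5dProfile, UtilityValueSet, apply_value_set, recode_severity

DIMS = ("mobility", "self_care", "usual_activities", "pain_discomfort",
        "anxiety_depression")

# synthetic decrements growing with severity; worst state lands below 0
decrements = {
    dim: {1: 0.0, 2: 0.04, 3: 0.09, 4: 0.18, 5: 0.28}
    for dim in DIMS
}
value_set = UtilityValueSet(decrements=decrements)

for levels in [(1, 1, 1, 1, 1), (2, 1, 1, 2, 3), (3, 3, 3, 3, 3), (5, 5, 5, 5, 5)]:
    profile = Eq5dProfile.from_levels(levels)
    u = apply_value_set(profile, value_set)
    print(f"profile {levels} -> utility {u:+.3f} "
          f"(reversed coding view {recode_severity(profile)})")

print("\nUtility 1 anchors full health; negative values are states valued "
      "worse than dead.")
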