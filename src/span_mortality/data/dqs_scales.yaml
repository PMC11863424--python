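# Default component scales for the 10-item diet quality score (DQS).
# Each component is scored 0 (unhealthiest) to 10 (healthiest) by linear
# interpolation between anchor_lo and anchor_hi, clamped.  healthy_high
# components score 0 at anchor_lo and 10 at anchor_hi; healthy_low
# components are reverse-scored (10 at anchor_lo, 0 at anchor_hi).
# Anchors are configuration data and may be overridden with a custom file.
components:
  vegetables:
    direction: healthy_high
    anchor_lo: 0.0
    anchor_hi: 3.0
    units: servings/day
  fruits:
    direction: healthy_high
    anchor_lo: 0.0
    anchor_hi: 3.0
    units: servings/day
  fish:
    direction: healthy_high
    anchor_lo: 0.0
    anchor_hi: 2.0
    units: servings/week
  dairy:
    direction: healthy_high
    anchor_lo: 0.0
    anchor_hi: 2.5
    units: servings/day
  whole_grains:
    direction: healthy_high
    anchor_lo: 0.0
    anchor_hi: 3.0
    units: servings/day
  vegetable_oils:
    direction: healthy_high
    anchor_lo: 0.0
    anchor_hi: 2.0
    units: tablespoons/day
  refined_grains:
    direction: healthy_low
    anchor_lo: 0.0
    anchor_hi: 2.0
    units: servings/week
  processed_meats:
    direction: healthy_low
    anchor_lo: 0.0
    anchor_hi: 2.0
    units: servings/week
  unprocessed_red_meats:
    direction: healthy_low
    anchor_lo: 0.0
    anchor_hi: 3.0
    units: servings/week
  sugar_sweetened_beverages:
    direction: healthy_low
    anchor_lo: 0.0
    anchor_hi: 1.0
    units: servings/day
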