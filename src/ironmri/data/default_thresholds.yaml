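# Literature-based default T2* severity boundaries (ms).
#
# These are conventional values from the clinical T2* literature, shipped
# as editable defaults — they are NOT constants verified against any single
# study, and sites should substitute their own reference ranges.
#
# Interpretation per organ, with boundaries b_severe < b_moderate < b_mild:
#   severe    t2star <  b_severe
#   moderate  b_severe  <= t2star < b_moderate
#   mild      b_moderate <= t2star < b_mild
#   normal    t2star >= b_mild
# A value exactly on a boundary belongs to the less-severe category.
heart:
  b_severe: 10.0
  b_moderate: 14.0
  b_mild: 20.0
liver:
  b_severe: 1.4
  b_moderate: 2.7
  b_mild: 6.3
pancreas:
  b_severe: 10.0
  b_moderate: 20.0
  b_mild: 26.0
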