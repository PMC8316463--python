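# Published obstacle conditions for the 213 cm walkway.
# am_*_override are the printed margin values; lateral offsets are chosen so
# the derived margins agree with the overrides to within 1 cm (see
# layout.derived_margins).  Condition 1 is the no-obstacle baseline.
conditions:
  1:
    obstacle_width: 0.0
  2:
    obstacle_width: 45.0
    obstacle_lateral_offset: 0.0
    am_left_override: 83.5
    am_right_override: 83.5
  3:
    obstacle_width: 90.0
    obstacle_lateral_offset: 0.0
    am_left_override: 61.0
    am_right_override: 61.0
  4:
    obstacle_width: 90.0
    obstacle_lateral_offset: 22.0
    am_left_override: 84.0
    am_right_override: 40.0
  5:
    obstacle_width: 90.0
    obstacle_lateral_offset: -22.0
    am_left_override: 40.0
    am_right_override: 84.0
  6:
    obstacle_width: 135.0
    obstacle_lateral_offset: 0.0
    am_left_override: 39.0
    am_right_override: 39.0
  7:
    obstacle_width: 135.0
    obstacle_lateral_offset: 13.5
    am_left_override: 52.0
    am_right_override: 25.0
  8:
    obstacle_width: 135.0
    obstacle_lateral_offset: -13.5
    am_left_override: 25.0
    am_right_override: 52.0
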