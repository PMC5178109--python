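# Default vital-sign score tables, age strata, temperature correction,
# color mapping and waiting-time policy.  Version: 2013-12 (final revision).
#
# Band convention: [lower, upper, score] with inclusive integer bounds;
# null means open-ended.  Measured values are rounded to the nearest
# integer (half away from zero) before lookup.  Overlapping bands are
# reported as warnings at load time and resolved in favour of the higher
# (more urgent) score.
version: "2013-12"

strata:
  # [id, lower_age_days inclusive, upper_age_days exclusive (null = unbounded)]
  - [NB_2MO, 0, 91]
  - [3_11MO, 91, 365]
  - [1_4Y, 365, 1826]
  - [5_12Y, 1826, 4749]
  - [GT_12Y, 4749, null]

domains:
  RR: [0, 250]
  HR: [0, 250]
  SPO2: [0, 100]

bands:
  NB_2MO:
    RR:
      - [null, 15, 4]
      - [16, 19, 2]
      - [20, 29, 1]
      - [30, 60, 0]
      - [61, 80, 2]
      - [81, 90, 3]
      - [91, null, 4]
    HR:
      - [null, 80, 4]
      - [81, 90, 2]
      - [91, 110, 1]
      - [111, 149, 0]
      - [150, 179, 2]
      - [180, 189, 3]
      - [190, null, 4]
    SPO2:
      - [null, 89, 4]
      - [90, 92, 2]
      - [93, 94, 1]
      - [95, 100, 0]
  3_11MO:
    RR:
      - [null, 15, 4]
      - [16, 19, 2]
      - [20, 24, 1]
      - [25, 50, 0]
      - [51, 70, 2]
      - [71, 80, 3]
      - [81, null, 4]
    HR:
      - [null, 70, 4]
      - [71, 80, 2]
      - [81, 100, 1]
      - [101, 139, 0]
      - [140, 169, 2]
      - [170, 179, 3]
      - [180, null, 4]
    SPO2:
      - [null, 89, 4]
      - [90, 92, 2]
      - [93, 94, 1]
      - [95, 100, 0]
  1_4Y:
    RR:
      - [null, 12, 4]
      - [13, 15, 2]
      - [16, 19, 1]
      - [20, 40, 0]
      - [41, 60, 2]
      - [61, 70, 3]
      - [71, null, 4]
    HR:
      - [null, 60, 4]
      - [61, 70, 2]
      - [71, 90, 1]
      - [91, 119, 0]
      - [120, 149, 2]
      - [150, 169, 3]
      - [170, null, 4]
    SPO2:
      - [null, 89, 4]
      - [90, 92, 2]
      - [93, 94, 1]
      - [95, 100, 0]
  5_12Y:
    RR:
      - [null, 10, 4]
      - [11, 14, 2]
      - [15, 17, 1]
      - [18, 24, 0]
      - [25, 36, 2]
      - [37, 50, 3]
      - [51, null, 4]
    HR:
      # NOTE: the published table prints "<51" followed by "50-60"; the
      # value 50 is claimed by both bands.  Kept verbatim; the loader
      # warns and the lookup resolves to the higher score (4).
      - [null, 50, 4]
      - [50, 60, 2]
      - [61, 70, 1]
      - [71, 109, 0]
      - [110, 129, 2]
      - [130, 149, 3]
      - [150, null, 4]
    SPO2:
      - [null, 89, 4]
      - [90, 92, 2]
      - [93, 94, 1]
      - [95, 100, 0]
  GT_12Y:
    RR:
      - [null, 9, 4]
      - [10, 10, 2]
      - [11, 11, 1]
      - [12, 16, 0]
      - [17, 22, 2]
      - [23, 29, 3]
      - [30, null, 4]
    HR:
      - [null, 40, 4]
      - [41, 50, 2]
      - [51, 60, 1]
      - [61, 99, 0]
      - [100, 119, 2]
      - [120, 139, 3]
      - [140, null, 4]
    SPO2:
      - [null, 89, 4]
      - [90, 92, 2]
      - [93, 94, 1]
      - [95, 100, 0]

# Correction applies only when the heart-rate sub-score is >= gate.
# 37.5 <= AxT <= 38.5 C subtracts 1; AxT > 38.5 C subtracts 2.
temp_correction:
  hr_score_gate: 2
  minus_one: [37.5, 38.5]   # inclusive on both edges
  minus_two_above: 38.5     # exclusive

# Total -> color (inclusive integer bands over the 0-12 range).
color_map:
  - [0, 0, BLUE]
  - [1, 2, GREEN]
  - [3, 5, YELLOW]
  - [6, 9, ORANGE]
  - [10, 12, RED]

# Final level -> (maximum waiting time in minutes, destination).
policy:
  RED: [0, resuscitation_room]
  ORANGE: [10, observation_room]
  YELLOW: [30, waiting_room]
  GREEN: [90, waiting_room]
  BLUE: [180, waiting_room]
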