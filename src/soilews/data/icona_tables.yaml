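# Default ICONA lookup matrices. Edit and pass to load_tables() to substitute
# an alternative reading (e.g. of the soil-protection matrix, whose published
# typesetting is ambiguous for the Sand Areas / Rangeland / Bare Land rows).
#
# slope_bins_pct: lower edges of the five slope classes (percent); intervals
#   are half-open [lo, hi), last bin unbounded above.
# cover_bins_pct: lower edges of the four vegetation-cover classes (percent);
#   half-open [lo, hi), last bin closed at 100.
slope_bins_pct: [0, 3, 12, 20, 35]
cover_bins_pct: [0, 25, 50, 75]

# erodibility[slope_class][lithofacies_class], classes 1..5 on both axes.
# Symbols: EN very low, EB low, EM moderate, EA high, EX very high.
erodibility:
  1: [EN, EN, EN, EN, EB]
  2: [EN, EN, EB, EM, EM]
  3: [EB, EB, EM, EA, EA]
  4: [EM, EM, EA, EX, EX]
  5: [EA, EA, EX, EX, EX]

# protection[land_use][cover_class], cover classes 1..4 (0-25, 25-50, 50-75, >75%).
# Symbols: MA very high conservation .. MB very low conservation.
protection:
  Dry Farming:       [MB, MB, B, B]
  Irrigated Farming: [MB, MB, B, M]
  Sand Areas:        [M,  M,  A, MA]
  Rangeland:         [MB, B,  M, A]
  Bare Land:         [M,  B,  MA, MA]
  Rock Outcrops:     [MA, MA, MA, MA]

# hazard[protection][erodibility], erodibility columns EN, EB, EM, EA, EX.
# Values are the five erosion-hazard classes 1 (shallow) .. 5 (very high).
hazard:
  MA: [1, 1, 1, 2, 2]
  A:  [1, 1, 2, 3, 4]
  M:  [1, 2, 3, 4, 4]
  B:  [2, 3, 3, 5, 5]
  MB: [2, 3, 4, 5, 5]
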