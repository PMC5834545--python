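# Steady-state calibration targets: literature intervals for the eight
# phosphoinositide pools of a resting (apical-like) plasma-membrane patch,
# in molecules per um^2, plus relative-order constraints between pools.
#
# PI(4,5)P2 ~ 10,000 molecules/um^2 is the well-established anchor; PI(4)P
# is comparable; PI dominates the inositol lipid pool; the 3-phosphorylated
# and 5-monophosphate pools are one to four orders of magnitude smaller.

intervals:
  "0":   {low: 50000, high: 300000}
  "3":   {low: 100,   high: 2000}
  "4":   {low: 5000,  high: 20000}
  "5":   {low: 50,    high: 1000}
  "34":  {low: 10,    high: 300}
  "35":  {low: 10,    high: 300}
  "45":  {low: 5000,  high: 20000}
  "345": {low: 0.5,   high: 50}

# each entry "a > b" requires pool a to exceed pool b at steady state
rank_constraints:
  - "0 > 4"
  - "0 > 45"
  - "4 > 3"
  - "45 > 3"
  - "3 > 34"
  - "3 > 35"
  - "5 > 345"
  - "34 > 345"
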