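"""Apical vs basolateral membrane configurations.

High PTEN / low PI3KI empties the PI(3,4,5)P3 pool (apical membrane);
low PTEN / high PI3KI fills it (~760 molecules/um^2, basolateral).  A
fast, SHIP1-like v345->34 shifts material from PI(3,4,5)P3 into
PI(3,4)P2.  From the apical state, a deep PTEN knockdown raises
PI(3,4,5)P3 sharply while leaving PI(4,5)P2 untouched.
"""

from pipkin.experiments import ExperimentRunner, run_membrane_polarity

runner = ExperimentRunner()
for config in ("apical", "basolateral"):
    for mode in ("slow", "fast"):
        res = run_membrane_polarity(config, mode, runner=runner)
        print(f"{config:12s} v345->34 {mode:4s}: PIP3 {res.abs('345'):8.1f}  "
              f"PI(3,4)P2 {res.abs('34'):6.1f}  PI(4,5)P2 {res.pct('45'):6.1f}% of basal")

for mode in ("slow", "fast"):
    kd = run_membrane_polarity("apical", mode, pten_knockdown=0.9833, runner=runner)
    print(f"apical + 98.33% PTEN kd ({mode:4s}): PIP3 {kd.abs('345'):8.1f}  "
          f"PI(4,5)P2 {kd.pct('45'):6.1f}% of basal")

print("\nPTEN and PI3KI alone switch the membrane between PIP3-poor and")
print("PIP3-rich states; PI(4,5)P2 stays put because PI(3,4,5)P3 turnover is")
print("tiny next to the PI(4,5)P2 pool.")
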