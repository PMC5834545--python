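# pipkin

Power-law kinetics of the plasma-membrane phosphoinositide pathway.

Phosphoinositides — PI and its seven phosphorylated derivatives — form a
dense interconversion network (21 enzymatic reactions among 8 lipid
species) that controls membrane identity, vesicular traffic and ion
channels.  PI(4,5)P₂ in particular gates the epithelial sodium channel
ENaC, making the pathway a therapeutic entry point in cystic fibrosis.
`pipkin` is for modellers and quantitative cell biologists who want to
interrogate this network in silico: which fluxes maintain PI(4,5)P₂,
what an enzyme knockdown does to every pool at once, and how well
steady-state data constrain the kinetic parameters.

## The model

A generalized mass action (GMA) system over molecule counts Xᵢ in a
homogeneous 1 µm² membrane patch:

    dXᵢ/dt = Σₛ v_{s→i} − Σₚ v_{i→p},    v_{i→j} = γ_{i→j} · E_{i→j} · Xᵢ^{f_{i→j}}

γ: rate constant, E: enzyme activity (mg/µm²), f: kinetic order.
Constant influxes supply PI, PI(4)P and PI(3)P from the ER, Golgi and
endosomes; all pools leave through first-order effluxes sharing one rate
constant, pinned so that 4.5 % of membrane phosphoinositides recycle per
minute.  On top of the dynamics the package provides:

* declarative perturbations (knockouts, knockdowns, overexpression, flux
  blocking) with protein-complex semantics, and a preset registry of the
  classic experiments;
* a calibration surface: literature intervals for all eight pools plus a
  13-entry registry of dynamic phenomena, scored as a sum of squared
  relative deviations;
* genetic-algorithm fitting and seeded Monte-Carlo exploration of
  parameter space with admissibility rules (pool intervals, pool-order
  constraints, influx < 25 % and efflux < 7 % of the receiving pool);
* local relative sensitivities S = ∂lnXᵢ*/∂ln p for every parameter, and
  the network of amplifying sensitivities |S| > 1;
* a synthetic-data generator (ground truths + noisy pseudo-observations)
  so estimation is testable end to end.

See `docs/methods.md` for assumptions, numerical choices and
limitations, and `docs/network.md` for the arrow-by-arrow map.

## Worked example

```python
from pipkin import load_network, find_steady_state
from pipkin.perturb import knockout_preset, apply
from pipkin.synthetic import reference_fixture

model = load_network()                 # shipped 8-species / 21-flux map
params = reference_fixture()           # calibrated reference parameters
basal = find_steady_state(model, params)
for sp in basal.species:
    print(sp, round(basal[sp], 1))

ko = find_steady_state(model, apply(params, knockout_preset("pip5ki_ko"), model))
print("PIP5KI knockout:", round(100 * ko["45"] / basal["45"], 1), "% of basal PI(4,5)P2")
```

prints

```
0 181084.5
3 400.4
4 10043.6
5 200.1
34 60.0
35 50.0
45 8246.3
345 2.0
PIP5KI knockout: 12.3 % of basal PI(4,5)P2
```

The basal state is an apical-like membrane: PI dominates (~1.8e5
molecules/µm²), PI(4)P and PI(4,5)P₂ sit near 10⁴, and PI(3,4,5)P₃ is
nearly absent (~2/µm²).  Knocking out PIP5KI removes both the canonical
PI(4)P → PI(4,5)P₂ flux and the PI4K+PIP5KI+DVL channelling complex, and
PI(4,5)P₂ collapses to ~13 % of basal — the strongest single-enzyme
handle on the pool, which is why PIP5KI (and the complex) are candidate
targets for lowering PI(4,5)P₂ and thereby ENaC activity.

More narrative examples live in `examples/` (steady state and flux
budget, the knockout panel, membrane polarity, sensitivity network,
Monte-Carlo identifiability, synthetic-data parameter recovery).  A thin
CLI wraps the same calls:

```sh
pipkin steady-state
pipkin perturb --preset sioss_x2
pipkin reproduce --figure 7
pipkin monte-carlo --n 1000 --seed 7
```

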