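# Plasma-membrane phosphoinositide interconversion network.
#
# One homogeneous 1 um^2 patch.  Species ids encode the phosphorylated
# positions of the inositol ring as digit strings ("0" = unphosphorylated
# PI, "345" = PI(3,4,5)P3), so that interconversion flux ids are mechanical:
# "v4->45" phosphorylates position 5 of PI(4)P.  Time unit: minutes.
#
# The map follows the canonical plasma-membrane network (Balla, Physiol Rev
# 2013) extended with direct PI -> PI(4,5)P2 channelling through a ternary
# PI4K+PIP5KI+DVL complex, its synaptojanin-mediated reversal
# PI(4,5)P2 -> PI, and the PI(4)P <-> PI(3,4)P2 pair.  Enzyme labels for
# two arrows are ambiguous in the literature and are flagged in
# docs/network.md (v0->3: class II/III PI 3-kinases, here "PI3KIII";
# v3->34: type II PIP kinase activity on PI(3)P, here grouped with PIP5KII).
#
# basal_abundance is the nominal literature mid-point used for calibration
# targets, in molecules per um^2.

time_unit: minute

species:
  - {id: "0",   name: "PI",          basal_abundance: 140000}
  - {id: "3",   name: "PI(3)P",      basal_abundance: 400}
  - {id: "4",   name: "PI(4)P",      basal_abundance: 10000}
  - {id: "5",   name: "PI(5)P",      basal_abundance: 200}
  - {id: "34",  name: "PI(3,4)P2",   basal_abundance: 60}
  - {id: "35",  name: "PI(3,5)P2",   basal_abundance: 50}
  - {id: "45",  name: "PI(4,5)P2",   basal_abundance: 10000}
  - {id: "345", name: "PI(3,4,5)P3", basal_abundance: 2}

# "components" marks protein complexes: perturbing a component enzyme also
# perturbs every complex that contains it (but not vice versa).
enzymes:
  - {id: PI4K}
  - {id: PIP5KI}
  - {id: PIP5KII}
  - {id: PI3KI}
  - {id: PI3KII}
  - {id: PI3KIII}
  - {id: PIKfyve}
  - {id: PTEN}
  - {id: SHIP}
  - {id: MTMR}
  - {id: SAC1}
  - {id: SAC3}
  - {id: INPP4}
  - {id: SYNJ}
  - {id: SIOSS}
  - {id: SYNJ_TMEM55}
  - {id: PI4K_PIP5KI_DVL, components: [PI4K, PIP5KI]}

fluxes:
  # --- phosphorylations (kinases) ---
  - {id: "v0->3",    kind: phosphorylation, substrate: "0",   product: "3",   enzyme: PI3KIII}
  - {id: "v0->4",    kind: phosphorylation, substrate: "0",   product: "4",   enzyme: PI4K}
  - {id: "v0->5",    kind: phosphorylation, substrate: "0",   product: "5",   enzyme: PIKfyve}
  - {id: "v0->45",   kind: phosphorylation, substrate: "0",   product: "45",  enzyme: PI4K_PIP5KI_DVL}
  - {id: "v3->34",   kind: phosphorylation, substrate: "3",   product: "34",  enzyme: PIP5KII}
  - {id: "v3->35",   kind: phosphorylation, substrate: "3",   product: "35",  enzyme: PIKfyve}
  - {id: "v4->34",   kind: phosphorylation, substrate: "4",   product: "34",  enzyme: PI3KII}
  - {id: "v4->45",   kind: phosphorylation, substrate: "4",   product: "45",  enzyme: PIP5KI}
  - {id: "v5->45",   kind: phosphorylation, substrate: "5",   product: "45",  enzyme: PIP5KII}
  - {id: "v45->345", kind: phosphorylation, substrate: "45",  product: "345", enzyme: PI3KI}
  # --- hydrolyses (phosphatases) ---
  - {id: "v3->0",    kind: hydrolysis, substrate: "3",   product: "0",  enzyme: MTMR}
  - {id: "v4->0",    kind: hydrolysis, substrate: "4",   product: "0",  enzyme: SAC1}
  - {id: "v34->3",   kind: hydrolysis, substrate: "34",  product: "3",  enzyme: INPP4}
  - {id: "v34->4",   kind: hydrolysis, substrate: "34",  product: "4",  enzyme: PTEN}
  - {id: "v35->3",   kind: hydrolysis, substrate: "35",  product: "3",  enzyme: SAC3}
  - {id: "v35->5",   kind: hydrolysis, substrate: "35",  product: "5",  enzyme: MTMR}
  - {id: "v45->0",   kind: hydrolysis, substrate: "45",  product: "0",  enzyme: SYNJ}
  - {id: "v45->4",   kind: hydrolysis, substrate: "45",  product: "4",  enzyme: SIOSS}
  - {id: "v45->5",   kind: hydrolysis, substrate: "45",  product: "5",  enzyme: SYNJ_TMEM55}
  - {id: "v345->34", kind: hydrolysis, substrate: "345", product: "34", enzyme: SHIP}
  - {id: "v345->45", kind: hydrolysis, substrate: "345", product: "45", enzyme: PTEN}
  # --- transport: influx from ER / Golgi / endosomes ---
  - {id: "v->0", kind: influx, product: "0"}
  - {id: "v->4", kind: influx, product: "4"}
  - {id: "v->3", kind: influx, product: "3"}
  # --- transport: first-order efflux, one shared rate constant ---
  - {id: "v0->",   kind: efflux, substrate: "0",   f: 1}
  - {id: "v3->",   kind: efflux, substrate: "3",   f: 1}
  - {id: "v4->",   kind: efflux, substrate: "4",   f: 1}
  - {id: "v5->",   kind: efflux, substrate: "5",   f: 1}
  - {id: "v34->",  kind: efflux, substrate: "34",  f: 1}
  - {id: "v35->",  kind: efflux, substrate: "35",  f: 1}
  - {id: "v45->",  kind: efflux, substrate: "45",  f: 1}
  - {id: "v345->", kind: efflux, substrate: "345", f: 1}
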