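# Perturbation preset registry: one entry per reported in-silico experiment.
#
# Scales multiply the reference value; overrides set absolute values.
# Enzyme knockouts are scale-0 entries on the enzyme group (scaling a
# component also removes any complex that contains it).  Flux blocking
# is expressed on gamma, matching the convention that a blocked reaction
# has its rate constant set to zero.

# --- single-enzyme knockdowns / knockouts -----------------------------------
pip5ki_ko:
  label: "PIP5KI knockout (removes v4->45 and the v0->45 complex)"
  enzyme_scales: {PIP5KI: 0}
pip5ki_half:
  label: "PIP5KI at 50% (heterozygous-like; scales E4->45 and E0->45)"
  enzyme_scales: {PIP5KI: 0.5}
pi4k_ko:
  label: "PI4K knockout (removes v0->4 and the v0->45 complex)"
  enzyme_scales: {PI4K: 0}
complex_ko:
  label: "PI4K+PIP5KI+DVL complex-only knockout (v0->45 only)"
  enzyme_scales: {PI4K_PIP5KI_DVL: 0}
pip5kii_ko:
  label: "PIP5KII knockout"
  enzyme_scales: {PIP5KII: 0}
pi3ki_ko:
  label: "PI3KI knockout"
  enzyme_scales: {PI3KI: 0}
pi3kii_ko:
  label: "PI3KII knockout"
  enzyme_scales: {PI3KII: 0}
pikfyve_ko:
  label: "PIKfyve knockout"
  enzyme_scales: {PIKfyve: 0}
mtmr_65:
  label: "MTMR reduced to 65% (MTMR2 knockdown surrogate)"
  enzyme_scales: {MTMR: 0.65}
sioss_x2:
  label: "SIOSS 5-phosphatases doubled"
  enzyme_scales: {SIOSS: 2}
synj_tmem55_x2:
  label: "SYNJ/TMEM55 phosphatases doubled"
  enzyme_scales: {SYNJ_TMEM55: 2}
pten_kd_9833:
  label: "PTEN knockdown of 98.33%"
  enzyme_scales: {PTEN: 0.0167}

# --- membrane configurations (absolute activities, mg/um^2) -----------------
apical:
  label: "apical-like membrane: high PTEN, low PI3KI"
  enzyme_overrides: {PTEN: 2.3e-15, PI3KI: 6.1e-16}
basolateral:
  label: "basolateral-like membrane: low PTEN, high PI3KI"
  enzyme_overrides: {PTEN: 3.9e-17, PI3KI: 1.5e-14}
ship_slow:
  label: "slow v345->34"
  gamma_overrides: {"v345->34": 1.0e+11}
  f_overrides: {"v345->34": 0.9982}
ship_fast:
  label: "fast v345->34 (SHIP1-like turnover)"
  gamma_overrides: {"v345->34": 6.0e+13}
  f_overrides: {"v345->34": 0.9998}

# --- PI-pool reduction experiments ------------------------------------------
pi_influx_half:
  label: "PI influx at 50% (halves the PI pool)"
  influx_scales: {"v->0": 0.5}
pi_drop_closed_transports:
  label: "PI influx at 50% with v->4 and v->3 closed"
  influx_scales: {"v->0": 0.5, "v->4": 0, "v->3": 0}
pi_drop_full_50pct:
  label: "v->4 = v->3 = 0 and v->0 at 2%"
  influx_scales: {"v->0": 0.02, "v->4": 0, "v->3": 0}

# --- source decomposition: stop all inputs into PI(4)P and PI(4,5)P2 --------
# Blocked inputs: v->4, v0->4 (gamma at 20% to avoid numerically tiny PI(4)P),
# v34->4, v45->4 and the direct PI(4,5)P2 sources v0->45, v5->45, v345->45.
# The conduit v4->45 stays active so that reactivating a PI(4)P source can
# feed PI(4,5)P2.  The reactivation presets leave exactly one input at its
# reference value.
fig3b_block_all_PI45P2_inputs:
  label: "all inputs into PI(4)P and PI(4,5)P2 stopped"
  influx_scales: {"v->4": 0}
  gamma_scales: {"v0->4": 0.2, "v34->4": 0, "v45->4": 0,
                 "v0->45": 0, "v5->45": 0, "v345->45": 0}
fig3b_only_v0_45:
  label: "only v0->45 re-activated"
  influx_scales: {"v->4": 0}
  gamma_scales: {"v0->4": 0.2, "v34->4": 0, "v45->4": 0,
                 "v5->45": 0, "v345->45": 0}
fig3b_only_v5_45:
  label: "only v5->45 re-activated"
  influx_scales: {"v->4": 0}
  gamma_scales: {"v0->4": 0.2, "v34->4": 0, "v45->4": 0,
                 "v0->45": 0, "v345->45": 0}
fig3b_only_v_4:
  label: "only the Golgi PI(4)P influx v->4 re-activated"
  gamma_scales: {"v0->4": 0.2, "v34->4": 0, "v45->4": 0,
                 "v0->45": 0, "v5->45": 0, "v345->45": 0}
fig3b_only_v345_45:
  label: "only v345->45 re-activated"
  influx_scales: {"v->4": 0}
  gamma_scales: {"v0->4": 0.2, "v34->4": 0, "v45->4": 0,
                 "v0->45": 0, "v5->45": 0}
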