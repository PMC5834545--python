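# The pathway map

The model covers the eight phosphoinositide species of a homogeneous
1 µm² patch of mammalian plasma membrane.  Species ids encode the
phosphorylated positions of the inositol ring, so flux labels are
mechanical: `v4->45` is the phosphorylation of PI(4)P at position 5.

| id | species | nominal pool (molecules/µm²) |
|------|---------------|--------|
| 0 | PI | 140,000 |
| 3 | PI(3)P | 400 |
| 4 | PI(4)P | 10,000 |
| 5 | PI(5)P | 200 |
| 34 | PI(3,4)P2 | 60 |
| 35 | PI(3,5)P2 | 50 |
| 45 | PI(4,5)P2 | 10,000 |
| 345 | PI(3,4,5)P3 | 2 |

The interconversion set (21 reactions) follows the canonical
plasma-membrane network of the review literature (Balla, *Physiol Rev*
93:1019, 2013; Sasaki et al., *Prog Lipid Res* 48:307, 2009), extended
with four fluxes that recent work supports: the direct channelling of PI
to PI(4,5)P2 by a ternary PI4K+PIP5KI+DVL complex (`v0->45`), its
synaptojanin-mediated reversal (`v45->0`, the 5-phosphatase domain feeding
the SAC1 domain), and the PI(4)P ↔ PI(3,4)P2 pair (`v4->34`, `v34->4`).

## Arrow-by-arrow enzyme assignment

Phosphorylations:

| flux | enzyme group | note |
|---------|---------------|------|
| v0->3 | PI3KIII | class II/III PI 3-kinases (Vps34 et al.); **ambiguous**, see below |
| v0->4 | PI4K | |
| v0->5 | PIKfyve | direct PI 5-phosphorylation |
| v0->45 | PI4K_PIP5KI_DVL | ternary complex; components PI4K, PIP5KI |
| v3->34 | PIP5KII | type II PIP kinase activity on PI(3)P; **ambiguous**, see below |
| v3->35 | PIKfyve | |
| v4->34 | PI3KII | class II PI 3-kinase on PI(4)P |
| v4->45 | PIP5KI | |
| v5->45 | PIP5KII | type II PIP kinases are PI(5)P 4-kinases |
| v45->345 | PI3KI | |

Hydrolyses:

| flux | enzyme group |
|---------|---------------|
| v3->0 | MTMR (myotubularins) |
| v4->0 | SAC1 |
| v34->3 | INPP4 |
| v34->4 | PTEN (minor PTEN activity on PI(3,4)P2) |
| v35->3 | SAC3 (FIG4) |
| v35->5 | MTMR |
| v45->0 | SYNJ (synaptojanin 5-phosphatase + SAC1 domains) |
| v45->4 | SIOSS (SYNJ1/2, INPP5B/J/E, OCRL1, SAC2, SKIP) |
| v45->5 | SYNJ_TMEM55 (4-phosphatases) |
| v345->34 | SHIP |
| v345->45 | PTEN |

Transport: influxes `v->0` (from the ER), `v->4` (from the Golgi),
`v->3` (from endosomes); one first-order efflux per species with a single
shared rate constant (fixed at 0.045 min⁻¹ so that 4.5% of membrane
phosphoinositides recycle per minute).

## Flagged ambiguities

Two arrows have genuinely ambiguous enzyme labels in the literature and
are flagged rather than silently resolved:

* **v0->3** — both class II (PI3K-C2) and class III (Vps34) 3-kinases
  produce PI(3)P.  The group is labelled `PI3KIII` and kept separate from
  `PI3KII` so that a PI3KII knockout affects only `v4->34`; merging the
  two groups would make a PI3KII knockout deplete PI(3)P, PI(3,5)P2 and
  PI(5)P as well.
* **v3->34** — the PI(3)P 4-kinase activity is a side activity of the
  type II PIP kinases; it is grouped under `PIP5KII`.  The flux is small
  at reference, so the assignment has little quantitative impact.

ATP/ADP/H2O/phosphate are assumed abundant and are not modelled; all
interconversions are 1:1 in lipid molecules, so stoichiometric
coefficients are all 1.
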