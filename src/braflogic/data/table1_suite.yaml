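# Literature-derived behaviors of the BRAF signaling model, encoded as
# baseline-vs-perturbed probability assertions on the t_end state
# distribution.  Rows without an explicit baseline compare against the
# unperturbed model under the same initial-condition profile.
- label: "1a: BRAF inhibition causes feedback activation of EGFR in colorectal context"
  perturbations: {BRAF: 0}
  profile: IC_CRC
  condition: {EGFR: 1}
  direction: increase
- label: "1b: no EGFR feedback activation after BRAF inhibition in melanoma context"
  perturbations: {BRAF: 0}
  profile: IC_melanoma
  condition: {EGFR: 1}
  direction: unchanged
- label: "2a: MEK inhibition stops the ERK signal"
  perturbations: {MEK: 0}
  profile: generic
  condition: {ERK: ">=1"}
  direction: decrease
- label: "2b: MEK inhibition activates the PI3K/AKT pathway"
  perturbations: {MEK: 0}
  profile: generic
  condition: {AKT: 1}
  direction: increase
- label: "2c: MEK inhibition increases ERBB3 activity"
  perturbations: {MEK: 0}
  profile: generic
  condition: {ERBB3: 1}
  direction: increase
# HGF rescue is assayed in a ligand-controlled context (no EGF/FGF/NRG1),
# mirroring stromal-HGF rescue experiments; the profile is given inline.
- label: "3: HGF signal confers resistance to BRAF inhibition"
  perturbations: {BRAF: 0, HGF: 1}
  baseline_perturbations: {BRAF: 0, HGF: 0}
  profile: {EGF: 0.0, FGF: 0.0, NRG1: 0.0}
  condition: {Proliferation: ">=1"}
  direction: increase
- label: "4a: BRAF inhibition in melanoma activates FOXD3"
  perturbations: {BRAF: 0}
  profile: IC_melanoma
  condition: {FOXD3: 1}
  direction: increase
- label: "4b: BRAF inhibition in melanoma activates ERBB3 via SOX10/FOXD3"
  perturbations: {BRAF: 0}
  profile: IC_melanoma
  condition: {ERBB3: 1}
  direction: increase
- label: "4c: BRAF inhibition in melanoma activates the PI3K/AKT axis"
  perturbations: {BRAF: 0}
  profile: IC_melanoma
  condition: {AKT: 1}
  direction: increase
- label: "5: constitutive CRAF reactivates ERK under BRAF inhibition"
  perturbations: {BRAF: 0, CRAF: 1}
  baseline_perturbations: {BRAF: 0}
  profile: generic
  condition: {ERK: ">=1"}
  direction: increase
- label: "6a: PTEN loss confers early resistance to BRAF inhibition"
  perturbations: {BRAF: 0, PTEN: 0}
  baseline_perturbations: {BRAF: 0}
  profile: generic
  condition: {Proliferation: ">=1"}
  direction: increase
- label: "6b: PI3K activation confers early resistance to BRAF inhibition"
  perturbations: {BRAF: 0, PI3K: 1}
  baseline_perturbations: {BRAF: 0}
  profile: generic
  condition: {Proliferation: ">=1"}
  direction: increase
- label: "6c: AKT activation confers early resistance to BRAF inhibition"
  perturbations: {BRAF: 0, AKT: 1}
  baseline_perturbations: {BRAF: 0}
  profile: generic
  condition: {Proliferation: ">=1"}
  direction: increase
- label: "7: combined BRAF + AKT inhibition overcomes resistance"
  perturbations: {BRAF: 0, AKT: 0}
  baseline_perturbations: {BRAF: 0}
  profile: generic
  condition: {Proliferation: ">=1"}
  direction: decrease
- label: "8a: BRAF inhibition induces the PI3K/AKT pathway"
  perturbations: {BRAF: 0}
  profile: generic
  condition: {AKT: 1}
  direction: increase
- label: "8b: EGFR inhibition does not block the AKT induction by BRAF inhibition"
  perturbations: {BRAF: 0, EGFR: 0}
  baseline_perturbations: {EGFR: 0}
  profile: generic
  condition: {AKT: 1}
  direction: increase
- label: "9: PI3K/AKT induction decreases sensitivity to MAPK inhibition"
  perturbations: {PI3K: 1, BRAF: 0}
  baseline_perturbations: {BRAF: 0}
  profile: generic
  condition: {Proliferation: ">=1"}
  direction: increase
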