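# Compound-specific in-vitro parameter registry for IDP-73152
# (aminopiperidine peptide-deformylase inhibitor, MW 554).
#
# All values are species means from the in-vitro assay program:
# Caco-2 bidirectional permeability, rapid-equilibrium-dialysis unbound
# fractions, blood partitioning, and microsomal / hepatocyte depletion.
# Units: Papp cm/s; CLint,mic uL/min/mg protein; CLint,hep uL/min/1e6 cells;
# blood clearance L/h/kg; Kp,ss dimensionless tissue:plasma.

name: IDP-73152
papp_a2b_cm_per_s: 31.2e-6
papp_b2a_cm_per_s: 49.5e-6

species:
  mouse:
    fu_p: 0.0562
    fu_mic: 0.571
    bp: 1.31
    clint_mic_ul_per_min_per_mg: 80.1
  rat:
    fu_p: 0.0582
    fu_mic: 0.439
    fu_hep: 0.492
    bp: 1.56
    clint_mic_ul_per_min_per_mg: 72.0
    clint_hep_ul_per_min_per_mcells: 27.7
    cl_blood_l_per_h_per_kg: 0.0430   # first-order loss in whole blood x blood volume x B:P
    observed_clp_l_per_h_per_kg: 2.00 # moment-analysis plasma clearance, 10 mg/kg IV
  dog:
    fu_p: 0.0547
    fu_mic: 0.507
    bp: 1.45
    clint_mic_ul_per_min_per_mg: 62.6
  human:
    fu_p: 0.0744
    fu_mic: 0.579
    bp: 1.24
    clint_mic_ul_per_min_per_mg: 31.8

# Steady-state tissue:plasma ratios measured in rats after a 10 h
# constant-rate infusion (0.8 mg/h). Other species are obtained by scaling
# Kp,ss in proportion to fu,p.
kp_ss_rat:
  adipose: 0.853
  brain: 0.0729
  heart: 2.15
  kidney: 8.68
  liver: 12.2
  lung: 7.13
  muscle: 1.37
  skin: 1.08
  spleen: 4.82
  testis: 0.338
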