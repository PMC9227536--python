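# Species physiology registry for the IDP-73152 PBPK model.
#
# Provenance tags used in comments:
#   [assay-implied] back-solved so that the whole-body model reproduces the
#                   in-vitro-scaled clearances / extraction ratios the drug
#                   registry encodes (see docs/methods.md); the literature
#                   alternative is kept alongside where it differs materially.
#   [literature]    standard reference physiology (Brown et al. 1997 /
#                   Davies & Morris 1993 style fractional organ weights and
#                   flows).
#
# Units: body weight kg; volumes as fraction of body weight (tissue density
# taken as 1 g/mL); blood volume L/kg; flows L/h/kg; GI rate constants 1/h.
# The ten perfusion-limited tissues are fixed: adipose, brain, heart, kidney,
# liver, lung, muscle, skin, spleen, testis.

species:
  rat:
    body_weight_kg: 0.2
    hematocrit: 0.46                 # [literature]
    blood_volume_l_per_kg: 0.0655    # 13.1 mL per 200 g rat [assay-implied]
    mppgl_mg_per_g: 45.0             # [literature] microsomal protein per g liver
    hpgl_million_per_g: 120.0        # [literature] hepatocellularity per g liver
    liver_density_g_per_ml: 1.07     # [literature]
    tissue_volume_fraction:
      adipose: 0.040                 # [literature]
      brain: 0.0048
      heart: 0.0040
      kidney: 0.0080
      liver: 0.078715                # [assay-implied] 15.74 mL / 200 g; see below
      lung: 0.0060
      muscle: 0.488
      skin: 0.160
      spleen: 0.0030
      testis: 0.010
    liver_volume_fraction_literature: 0.040   # ~8 g liver per 200 g rat
    blood_flow_l_per_h_per_kg:
      adipose: 0.40                  # [literature]
      brain: 0.13
      heart: 0.33
      kidney: 0.92
      muscle: 1.83
      skin: 0.38
      spleen: 0.10
      testis: 0.03
      hepatic_artery: 4.78           # [assay-implied] total liver inflow 4.88 L/h/kg
    gi:
      ks_per_h: 4.0                  # [literature] fasted gastric emptying
      kt_small_per_h: 2.0            # [literature] 3 segments / 1.5 h SI transit
      kt_large_per_h: 0.2857         # [literature] 2 segments / 7 h colonic transit
      sf: 0.297                      # fitted interspecies absorption scale factor
      asf: 0.0568                    # fitted large-intestinal scale factor
  mouse:
    body_weight_kg: 0.02
    hematocrit: 0.45
    blood_volume_l_per_kg: 0.080
    mppgl_mg_per_g: 45.0
    liver_density_g_per_ml: 1.07
    tissue_volume_fraction:
      adipose: 0.070
      brain: 0.0165
      heart: 0.0050
      kidney: 0.0167
      liver: 0.0665                  # [assay-implied] 1.33 mL / 20 g
      lung: 0.0073
      muscle: 0.384
      skin: 0.1653
      spleen: 0.0035
      testis: 0.010
    liver_volume_fraction_literature: 0.055
    blood_flow_l_per_h_per_kg:
      adipose: 0.50
      brain: 0.20
      heart: 0.40
      kidney: 1.30
      muscle: 2.20
      skin: 0.50
      spleen: 0.15
      testis: 0.05
      hepatic_artery: 10.0275        # [assay-implied] total liver inflow 10.18 L/h/kg
    gi:
      ks_per_h: 6.0
      kt_small_per_h: 2.0
      kt_large_per_h: 0.2857
      sf: 0.446
      asf: 0.0973
  dog:
    body_weight_kg: 10.0
    hematocrit: 0.42
    blood_volume_l_per_kg: 0.082
    mppgl_mg_per_g: 45.0
    liver_density_g_per_ml: 1.07
    tissue_volume_fraction:
      adipose: 0.150
      brain: 0.0080
      heart: 0.0080
      kidney: 0.0055
      liver: 0.03028                 # [assay-implied]; matches ~3% BW literature liver
      lung: 0.0089
      muscle: 0.457
      skin: 0.0911
      spleen: 0.0027
      testis: 0.0010
    liver_volume_fraction_literature: 0.0329
    blood_flow_l_per_h_per_kg:
      adipose: 0.18
      brain: 0.05
      heart: 0.25
      kidney: 1.05
      muscle: 1.00
      skin: 0.30
      spleen: 0.08
      testis: 0.01
      hepatic_artery: 3.38126        # [assay-implied] total liver inflow 3.461 L/h/kg
    gi:
      ks_per_h: 2.5
      kt_small_per_h: 1.5            # 3 segments / 2 h SI transit
      kt_large_per_h: 0.16667        # 2 segments / 12 h colonic transit
      sf: 1.31
      asf: null                      # large-intestinal scaling not used in dogs
  human:
    body_weight_kg: 70.0
    hematocrit: 0.45
    blood_volume_l_per_kg: 0.079
    mppgl_mg_per_g: 39.8
    liver_density_g_per_ml: 1.07
    intestinal_radius_cm: 1.53       # small-intestinal radius for ka = 2*Peff/R
    tissue_volume_fraction:
      adipose: 0.214
      brain: 0.020
      heart: 0.0047
      kidney: 0.0044
      liver: 0.021                   # [assay-implied] 1.47 L; literature ~1.8 L
      lung: 0.0076
      muscle: 0.400
      skin: 0.0371
      spleen: 0.0026
      testis: 0.0005
    liver_volume_fraction_literature: 0.0257
    blood_flow_l_per_h_per_kg:
      adipose: 0.24
      brain: 0.58
      heart: 0.19
      kidney: 0.91
      muscle: 0.82
      skin: 0.24
      spleen: 0.045
      testis: 0.003
      hepatic_artery: 1.197857       # [assay-implied] total liver inflow 87 L/h / 70 kg
    gi:
      ks_per_h: 2.8
      kt_small_per_h: 0.903614       # 3 segments / 3.32 h SI transit
      kt_large_per_h: 0.148148       # 2 segments / 13.5 h colonic transit
      sf: 1.0
      asf: null
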