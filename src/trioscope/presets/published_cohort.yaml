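# Cohort-shaped simulation preset: subgroup mix, per-subgroup solve
# probabilities, inheritance-mode mix among solved families, consanguinity
# rate and proband sex ratio follow the published cohort fractions.
n_families: 1000
seed: 1
subgroup_probs:
  NDD_ONLY: 0.076
  NDD_SYNDROME: 0.489
  SYNDROME: 0.370
  FETUS: 0.065
solved_prob_per_subgroup:
  NDD_ONLY: 0.329
  NDD_SYNDROME: 0.462
  SYNDROME: 0.335
  FETUS: 0.277
mode_probs:
  AD_DENOVO: 0.4515306122448980
  XL_DENOVO: 0.0586734693877551
  AR_HOM: 0.2117346938775510
  AR_COMPHET: 0.1071428571428571
  XL_MATERNAL: 0.0688775510204082
  AD_INHERITED: 0.0969387755102041
  PARENTAL_MOSAIC_MATERNAL: 0.0025510204081633
  PARENTAL_MOSAIC_PATERNAL: 0.0025510204081632
consanguinity_prob: 0.103
consang_ar_hom_boost: 4.0
dual_diagnosis_prob: 0.048
background_variants_per_family: 300
background_af_distribution:
  p_rare: 0.6
  rare_max: 0.009
  common_min: 0.02
  common_max: 0.5
background_offtarget_prob: 0.3
mean_depth: 30
base_error: 0.0
mosaic_fraction_range: [0.05, 0.14]
male_prob: 0.59
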