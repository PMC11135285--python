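# Default parameters of the synthetic aMCI cohort simulator (version 1).
#
# Baseline means/sds of demographics, cognitive scores, APOE carrier rates and
# Centiloid are set per amyloid group to the published baseline characteristics
# of an amnestic-MCI clinic cohort (abeta_neg n=312 / abeta_pos n=345).
# MRI cortical-thickness and hippocampal baselines are not published there and
# are set to field-typical values (mean regional cortical thickness ~2.3-2.6 mm,
# hippocampal volume / intracranial volume ~0.0045). Annual slopes are chosen so
# the abeta_pos group declines strictly faster on every marker, CDR-SB being the
# one score that increases with worsening. Slopes, loadings and noise sds are
# simulator choices (the generative model is the package's own); see
# docs/methods.md for rationale.
version: 1
n_subjects: 200          # per group
n_visits: 4              # annual visits: baseline + 3 follow-ups
p_miss: 0.2              # intermittent missingness, non-baseline visits
p_drop: 0.18             # per-visit dropout hazard; mean follow-up ~2.1 of 3 years
apoe_rate: {abeta_neg: 0.170, abeta_pos: 0.646}
female_rate: {abeta_neg: 0.506, abeta_pos: 0.609}
age: {mean: {abeta_neg: 71.0, abeta_pos: 72.0}, sd: 8.2}
education: {mean: {abeta_neg: 12.4, abeta_pos: 11.8}, sd: 4.5}
centiloid: {mean: {abeta_neg: 7.5, abeta_pos: 90.9}, sd: {abeta_neg: 18.8, abeta_pos: 31.1}}
features:
  ct_cingulate:    {mean: {abeta_neg: 2.55, abeta_pos: 2.50}, sd: {abeta_neg: 0.12, abeta_pos: 0.12}, slope: {abeta_neg: -0.015, abeta_pos: -0.045}, loading: -0.04, noise_sd: 0.02}
  ct_frontal:      {mean: {abeta_neg: 2.45, abeta_pos: 2.41}, sd: {abeta_neg: 0.12, abeta_pos: 0.12}, slope: {abeta_neg: -0.013, abeta_pos: -0.040}, loading: -0.04, noise_sd: 0.02}
  ct_parietal:     {mean: {abeta_neg: 2.40, abeta_pos: 2.36}, sd: {abeta_neg: 0.12, abeta_pos: 0.12}, slope: {abeta_neg: -0.014, abeta_pos: -0.042}, loading: -0.04, noise_sd: 0.02}
  ct_temporal:     {mean: {abeta_neg: 2.60, abeta_pos: 2.54}, sd: {abeta_neg: 0.13, abeta_pos: 0.13}, slope: {abeta_neg: -0.016, abeta_pos: -0.048}, loading: -0.05, noise_sd: 0.02}
  ct_occipital:    {mean: {abeta_neg: 2.30, abeta_pos: 2.27}, sd: {abeta_neg: 0.11, abeta_pos: 0.11}, slope: {abeta_neg: -0.012, abeta_pos: -0.038}, loading: -0.03, noise_sd: 0.02}
  hippocampus_icv: {mean: {abeta_neg: 0.0046, abeta_pos: 0.0043}, sd: {abeta_neg: 0.0004, abeta_pos: 0.0004}, slope: {abeta_neg: -0.00008, abeta_pos: -0.00024}, loading: -0.00015, noise_sd: 0.00006}
  dsf:             {mean: {abeta_neg: 5.9, abeta_pos: 5.9}, sd: {abeta_neg: 1.4, abeta_pos: 1.4}, slope: {abeta_neg: -0.05, abeta_pos: -0.15}, loading: -0.4, noise_sd: 0.5}
  kbnt:            {mean: {abeta_neg: 43.2, abeta_pos: 42.3}, sd: {abeta_neg: 9.3, abeta_pos: 9.4}, slope: {abeta_neg: -0.5, abeta_pos: -1.5}, loading: -3.0, noise_sd: 2.0}
  rcft_copy:       {mean: {abeta_neg: 30.8, abeta_pos: 29.1}, sd: {abeta_neg: 5.7, abeta_pos: 7.5}, slope: {abeta_neg: -0.4, abeta_pos: -1.2}, loading: -2.0, noise_sd: 1.5}
  svlt_delayed:    {mean: {abeta_neg: 3.4, abeta_pos: 1.6}, sd: {abeta_neg: 2.5, abeta_pos: 2.1}, slope: {abeta_neg: -0.15, abeta_pos: -0.45}, loading: -0.8, noise_sd: 0.7}
  rcft_delayed:    {mean: {abeta_neg: 9.0, abeta_pos: 4.7}, sd: {abeta_neg: 6.1, abeta_pos: 4.3}, slope: {abeta_neg: -0.4, abeta_pos: -1.0}, loading: -1.8, noise_sd: 1.5}
  cowat:           {mean: {abeta_neg: 22.2, abeta_pos: 22.7}, sd: {abeta_neg: 10.0, abeta_pos: 12.0}, slope: {abeta_neg: -0.5, abeta_pos: -1.5}, loading: -3.0, noise_sd: 2.5}
  stroop_color:    {mean: {abeta_neg: 72.5, abeta_pos: 63.2}, sd: {abeta_neg: 26.4, abeta_pos: 28.4}, slope: {abeta_neg: -2.0, abeta_pos: -6.0}, loading: -8.0, noise_sd: 5.0}
  kmmse:           {mean: {abeta_neg: 26.8, abeta_pos: 25.1}, sd: {abeta_neg: 2.4, abeta_pos: 3.3}, slope: {abeta_neg: -0.3, abeta_pos: -0.9}, loading: -0.8, noise_sd: 0.6}
  cdr_sb:          {mean: {abeta_neg: 1.3, abeta_pos: 1.9}, sd: {abeta_neg: 0.9, abeta_pos: 1.2}, slope: {abeta_neg: 0.3, abeta_pos: 0.8}, loading: 0.4, noise_sd: 0.3}
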