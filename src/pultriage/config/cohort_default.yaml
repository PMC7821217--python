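# Default ("table1-like") synthetic cohort profile.  These values mirror
# CohortConfig's defaults; edit a copy to produce harder/easier cohorts.
n: 2899
centre_fractions: [0.25, 0.18, 0.15, 0.14, 0.10, 0.08, 0.06, 0.04]
outcome_prevalences: [0.51422, 0.35742, 0.12836]   # FPUL / IUP / EP
centre_ep_tilt_sd: 0.2
biomarkers:
  FPUL: {mu_log_hcg0: 6.05, sd_log_hcg0: 1.50, mu_log_ratio: -0.80,
         sd_log_ratio: 0.65, mu_log_prog0: 1.39, sd_log_prog0: 1.39,
         rho_hcg_prog: 0.3}
  IUP:  {mu_log_hcg0: 6.45, sd_log_hcg0: 1.60, mu_log_ratio: 0.65,
         sd_log_ratio: 0.45, mu_log_prog0: 3.69, sd_log_prog0: 0.75,
         rho_hcg_prog: 0.3}
  EP:   {mu_log_hcg0: 6.33, sd_log_hcg0: 1.40, mu_log_ratio: 0.05,
         sd_log_ratio: 0.35, mu_log_prog0: 2.30, sd_log_prog0: 0.90,
         rho_hcg_prog: 0.3}
prog_supplement_rate: 0.02
prog_missing_rate: 0.06
hcg48_missing_base: 0.073
hcg48_missing_beta_hcg: -0.15
hcg48_missing_beta_bleed: 0.10
step1_compliance: 0.25
ltfu_rate: 0.10
ltfu_beta_ratio: -0.35
ltfu_beta_bleed: 0.10
interval_probs: {1: 0.05, 2: 0.86, 3: 0.06, 4: 0.02, 5: 0.01}
seed: 0
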