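# SYNTHETIC stand-in coefficient sets for the M4 / M6NP / M6P multinomial
# PUL risk models.  These are NOT the published coefficients: they were
# obtained by fitting each model's basis (multinomial logistic regression,
# reference category FPUL) to a large cohort drawn from this package's
# synthetic-cohort generator, so they reproduce the models' structure and
# qualitative behaviour (M6P discriminates best, progesterone-free models
# worse) on generator-like data.  To validate the real models, replace
# this file with a transcription of the published formulas; the engine is
# generic over basis terms.
#
# Units are fixed: hCG in IU/l, progesterone in nmol/l.
models:
  - model: M6P
    reference: FPUL
    units: {hcg: IU/l, progesterone: nmol/l}
    basis:
      - {name: intercept, variable: one, transform: one}
      - {name: log_hcg0, variable: hcg0, transform: log}
      - {name: log_ratio, variable: hcg_ratio, transform: log}
      - {name: log_ratio_sq, variable: hcg_ratio, transform: squared_log}
      - {name: log_prog0, variable: prog0, transform: log}
    beta_iup: [-5.2699, -0.2985, 5.5549, -1.8940, 2.4852]
    beta_ep: [-1.0752, -0.0228, 2.3027, -2.9177, 0.6429]
  - model: M6NP
    reference: FPUL
    units: {hcg: IU/l, progesterone: nmol/l}
    basis:
      - {name: intercept, variable: one, transform: one}
      - {name: log_hcg0, variable: hcg0, transform: log}
      - {name: log_ratio, variable: hcg_ratio, transform: log}
      - {name: log_ratio_sq, variable: hcg_ratio, transform: squared_log}
    beta_iup: [-1.3289, 0.1660, 5.1159, -1.2816]
    beta_ep: [-0.7887, 0.1249, 2.3064, -2.8818]
  - model: M4
    reference: FPUL
    units: {hcg: IU/l, progesterone: nmol/l}
    basis:
      - {name: intercept, variable: one, transform: one}
      - {name: log_hcg0, variable: hcg0, transform: log}
      - {name: log_ratio, variable: hcg_ratio, transform: log}
    beta_iup: [-1.5695, 0.1708, 5.6894]
    beta_ep: [-1.2254, 0.1234, 2.7484]

# Two-step triage strategy constants.
step1:
  progesterone_cutoff: 2.0   # nmol/l, inclusive
  risk_triple: [0.961, 0.022, 0.017]   # (FPUL, IUP, EP)
ep_risk_threshold: 0.05       # >= threshold flags high risk of EP
hcg_ratio_cutoffs: [0.87, 1.66]   # inclusive high-risk band
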