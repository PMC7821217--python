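# pultriage

Validation toolkit for triage of **pregnancies of unknown location (PUL)** —
pregnancies with a positive test but no location visible on transvaginal
ultrasound. A PUL ends as a failing pregnancy (FPUL), an intrauterine
pregnancy (IUP) or an ectopic pregnancy (EP, including persistent PUL); the
clinical task is to keep close follow-up focused on the women at risk of EP
while sparing the rest unnecessary visits.

The package is written for biostatisticians and clinical-prediction-model
researchers who need to externally validate PUL triage approaches on
multi-centre cohorts. It implements both the **triage strategies** and the
complete **validation machinery** around them.

## Models and strategies

The M4 and M6 families are multinomial logistic models over the three
outcomes with FPUL as the reference category. With basis terms
$x = \big(1, \log h_0, \log r, (\log r)^2 [, \log p_0]\big)$ built from the
initial serum beta-hCG $h_0$ (IU/l), the 48-hour hCG ratio
$r = h_{48}/h_0$, and (for M6P) the initial progesterone $p_0$ (nmol/l):

$$\eta_{\mathrm{IUP}} = \beta_{\mathrm{IUP}}^\top x,\qquad
  \eta_{\mathrm{EP}} = \beta_{\mathrm{EP}}^\top x,\qquad
  \eta_{\mathrm{FPUL}} = 0,$$

$$P(k \mid x) = \frac{e^{\eta_k}}{\sum_j e^{\eta_j}},\qquad
  k \in \{\mathrm{FPUL}, \mathrm{IUP}, \mathrm{EP}\}.$$

Strategies evaluated side by side:

* **2ST** (two-step triage): Step 1 discharges as low risk any woman with
  $p_0 \le 2$ nmol/l, assigning the fixed risk triple (0.961, 0.022, 0.017);
  Step 2 applies M6P to the remainder;
* **M6P / M6NP / M4** alone, flagging high risk of EP when
  $\hat P(\mathrm{EP}) \ge 5\%$ (a threshold whose odds imply accepting up
  to 19 false positives per detected EP);
* **hCG-ratio cut-offs**: $r < 0.87$ → FPUL, $0.87 \le r \le 1.66$ → high
  risk of EP, $r > 1.66$ → IUP (a 13% fall to a 66% rise over 48 h).

Coefficients are *data, not code*: the engine is generic over basis terms
and reads a YAML/JSON config. The shipped file
(`pultriage/config/coefficients_synthetic.yaml`) is a clearly-labelled
synthetic stand-in fitted to this package's own cohort generator — swap in
a transcription of the published formulas to validate the real models.

## Validation machinery

* **Discrimination** — binary AUC for EP, FPUL-vs-IUP AUC by the
  conditional-risk method, and the polytomous discrimination index (PDI),
  with a DeLong standard error per centre;
* **Calibration** — intercept (slope fixed at 1) and slope of logistic
  recalibration on $\mathrm{logit}(\hat P(\mathrm{EP}))$, with random
  intercept and slope by centre fitted by adaptive Gauss–Hermite maximum
  likelihood, plus smooth (spline-based) calibration curves;
* **Clinical utility** — Net Benefit
  $\mathrm{NB}(t) = \mathrm{TP}/n - (\mathrm{FP}/n)\,t/(1-t)$ and decision
  curves over 3–10% thresholds against treat-all / treat-none;
* **Meta-analysis** — random-effects pooling (REML $\tau^2$) of
  centre-specific metrics with 95% confidence and 95% prediction intervals;
* **Missing data** — protocol rules (a second hCG not taken at a 2-day
  interval is missing; progesterone under supplements is missing), chained
  multiple imputation (PMM for log-biomarkers, multinomial draws for the
  outcome of women lost to follow-up) and Rubin pooling;
* **Synthetic cohorts** — a generator reproducing the outcome mix,
  biomarker distributions, centre clustering and missingness profile of a
  realistic multi-centre PUL cohort, since no such dataset is public.

## Worked example

```python
import pultriage as pt

cfg = pt.CohortConfig(n=2899, seed=4)
cohort, rates = pt.inject_missingness(pt.generate_cohort(cfg), cfg)

config = pt.AnalysisConfig(strategies=("2ST", "M6P"), m_imputations=5, seed=2)
results = pt.PULValidation(cohort, config).fit()
print(results.summary())
```

Output of the equivalent CLI run
(`pultriage simulate --n 900 --seed 4 --out cohort.csv` followed by
`pultriage validate --cohort cohort.csv --m 1 --seed 2 --strategies 2ST,M6P
--nb-bootstrap 100 --out report/`):

```
External validation of PUL triage strategies
============================================================
records: 796   centres: 8   imputations: 1   mode: primary
EP-risk threshold: 5%   Step 1 low-risk fraction: 15.3%

Discrimination (random-effects pooled across centres)
------------------------------------------------------------
metric    auc_ep  auc_fpul_iup    pdi
strategy
2ST        0.886         0.996  0.881
M6P        0.877         0.996  0.874

Classification at the EP-risk threshold
------------------------------------------------------------
metric    pct_low_risk  sensitivity    fpr    ppv    npv
strategy
2ST              0.572        0.885  0.347  0.310  0.972
M6P              0.518        0.931  0.405  0.277  0.978

Calibration of the estimated EP risk
------------------------------------------------------------
          intercept  slope
strategy
2ST           0.127  1.051
M6P           0.021  1.116

Net Benefit at 5% (pooled)
------------------------------------------------------------
           2ST: model +0.1007   treat-all +0.0811   harmful: False
           M6P: model +0.1073   treat-all +0.0838   harmful: False
```

Reading it: 796 of the 900 simulated women were eligible and not lost to
follow-up; Step 1 discharged 15.3% of them on progesterone alone. Both
strategies discriminate EP well (pooled AUC ≈ 0.88), risks are close to
calibrated (slope near 1, intercept near 0), and at a 5% threshold both
beat the treat-all and treat-none defaults — M6P finds more EPs
(sensitivity 0.93 vs 0.89) at the price of more false positives (FPR 0.41
vs 0.35). `results.forest("auc_ep", "M6P")` returns the centre-level
forest-plot data behind any pooled number; `results.to_csv_dir()` exports
the whole report bundle.

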