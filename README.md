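# shiftmon

Longitudinal model-shift monitoring for clinical risk prediction scores.

Machine-learning risk models deployed in hospitals (predicting acute kidney
injury, sepsis, delirium, …) degrade silently as clinical practice, coding
policies and patient populations evolve. Monitoring only discrimination
(AUROC) misses the most common failure mode: a **calibration shift**, where
predicted probabilities drift away from observed event rates while the
ranking of patients — and hence the AUROC — is untouched. `shiftmon`
implements a four-stage monitoring methodology for a table of scored cases
(one probability per hospital stay, one binary outcome, one time period):

1. **Cohort profiling** — per-period case counts, incidence and score
   ranges, flagging periods whose incidence hints at labelling changes.
2. **Discrimination stability** — per-period AUROC $A$ and AUPRC, the
   Hanley–McNeil standard error
   $SE(A)^2 = \frac{A(1-A) + (n_+{-}1)(Q_1 - A^2) + (n_-{-}1)(Q_2 - A^2)}{n_+ n_-}$
   with $Q_1 = A/(2-A)$, $Q_2 = 2A^2/(1+A)$, and independent-samples
   Z-tests $Z = (A_a - A_b)/\sqrt{SE_a^2 + SE_b^2}$ between periods.
3. **Calibration shift** — Platt scaling
   $p = \big(1 + e^{A f + B}\big)^{-1}$, $f = \mathrm{logit}(\text{raw score})$,
   fitted by maximum likelihood on a reserved calibration split;
   quantile-binned reliability curves with Wilson 95% CIs; ECE/MCE per
   period; a shift flag when a period's post-calibration ECE exceeds the
   calibration split's by a margin (default 0.05).
4. **Decision impact** — operating threshold minimising
   $|\mathrm{FNR} - \mathrm{FPR}|$ (under- vs overdiagnosis), alert rates,
   five-category alert outcomes, decision-curve analysis with
   $\mathrm{NB}(p_t) = \frac{TP}{N} - \frac{FP}{N}\frac{p_t}{1-p_t}$,
   incidence standardisation across periods, and an unpaired bootstrap test
   comparing two periods' net-benefit curves.

Because real hospital EHR data cannot ship with a package, `shiftmon` also
contains a first-class synthetic cohort simulator: an equal-variance
binormal latent model with closed-form AUROC
$\Phi\!\big(\Delta/(\sigma\sqrt{2})\big)$, an exactly logistic Bayes
posterior (so "perfectly calibrated" is well defined), and injectable
logit-affine miscalibration, downsampling and incidence thinning — every
monitoring stage is validated against this known ground truth.

## Worked example

Inject a one-logit overestimation drift into the final period only
(`examples/calibration_shift.py`):

```python
from shiftmon import CohortConfig, auroc, calibration_shift_report, generate_cohort

cohort = generate_cohort(
    CohortConfig(n_per_period=20_000, miscal_offset=(0.0, 0.0, 0.0, 1.0), seed=7)
)
report = calibration_shift_report(cohort, n_bins=10, margin=0.05)
```

prints

```
calibration-split ECE after Platt scaling: 0.0065

2018: AUROC 0.9230 | ECE raw 0.0032 -> calibrated 0.0174 | MCE calibrated 0.0696
2019: AUROC 0.9253 | ECE raw 0.0049 -> calibrated 0.0167 | MCE calibrated 0.0621
2020: AUROC 0.9186 | ECE raw 0.0034 -> calibrated 0.0187 | MCE calibrated 0.0595
2021: AUROC 0.9239 | ECE raw 0.0828 -> calibrated 0.0574 | MCE calibrated 0.1485  <-- CALIBRATION SHIFT
```

All four AUROCs sit within sampling error of the generator's true 0.9214 —
the drifted period is indistinguishable by discrimination — while its raw
ECE is 17–26× that of the clean periods and its post-calibration ECE still
exceeds the calibration-split benchmark (0.0065) by more than the 0.05
margin, so only 2021 is flagged. Other examples cover cohort simulation,
AUROC stability testing, decision-curve comparison, and the full pipeline
(`examples/*.py`), which is also available from the shell:

```bash
shiftmon simulate --config cfg.yaml --seed 7 --out cohort.csv
shiftmon profile cohort.csv
shiftmon evaluate --input cohort.csv --out-dir run/
shiftmon compare --input cohort.csv --pair 2020 2021
```

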