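# Methods

## The monitoring problem

A clinical risk model deployed in an EHR emits one probability per hospital
stay; at discharge the outcome label becomes known. Over calendar periods
the data-generating environment drifts — coding policies, clinical
protocols, patient mix — and the model can fail in three distinguishable
ways: its *discrimination* can degrade (positives no longer outrank
negatives), its *calibration* can shift (probabilities no longer match
event rates), or its *decision value* can erode (the alerting policy built
on it stops being better than treat-all/treat-none). `shiftmon` tests each
axis separately because they are statistically independent failure modes: a
strictly monotone distortion of the scores changes calibration and decision
behaviour while leaving every rank statistic — including AUROC — exactly
fixed.

## Synthetic cohort model

The simulator is an equal-variance binormal latent model. For period $y$
with incidence $\pi_y$: the label is Bernoulli($\pi_y$); a latent score
$z \sim N(\mu_+,\sigma)$ for cases and $N(\mu_-,\sigma)$ for controls. Two
properties make this family the right validation substrate:

* the true AUROC has the closed form $\Phi(\Delta/(\sigma\sqrt2))$ with
  $\Delta = \mu_+ - \mu_-$, giving an analytic oracle for discrimination;
* the Bayes posterior $P(\text{case}\mid z)$ is *exactly* logistic in $z$,
  $\mathrm{logit}\,p = \mathrm{logit}\,\pi_y + \frac{\Delta}{\sigma^2}\big(z - \tfrac{\mu_++\mu_-}{2}\big)$,
  so "perfectly calibrated" is well defined and stored as `true_prob`.

Miscalibration is injected on the logit scale,
`raw_score = sigmoid(a_mis * logit(true_prob) + b_mis)` — precisely the
affine family that Platt scaling inverts, so an injected drift
$(a, b)$ is recoverable as the fitted $(A, B) = (-1/a,\; b/a)$, and
recovery error is a direct measure of correctness rather than an
approximation gap. A positive offset makes the model overestimate risk, the
direction deployed clinical models typically err in.

### Defaults (the study conditions)

| parameter | default | rationale |
|---|---|---|
| periods | 4 yearly labels | a multi-year monitoring horizon |
| `n_per_period` | 20,000 | desk-scale stand-in for ~190k-case hospital datasets |
| `incidence` | 0.15 | an AKI-like use case — the high-incidence condition on which scale/incidence experiments are feasible |
| `mu_pos - mu_neg`, `sigma` | 2, 1 | true AUROC 0.9214, the realistic 0.90+ regime of published inpatient risk models |
| `a_mis, b_mis` | 1, 0 | calibrated unless drift is injected |
| `calib_fraction` | 0.10 | the conventional reserved validation/calibration/threshold split |

Optional onset/stay times (`with_times`): length of stay is a rounded
exponential (mean 7 days, capped at 90); onset is uniform on $[0,
\text{los}]$ for cases. These exist solely to exercise the five-category
alert classifier; real onset processes are not modelled.

What the simulator deliberately does **not** emulate: EHR features, within-
stay score trajectories (one score per case, an end-of-stay evaluation),
correlated case mix across periods, or seasonal structure. Passing tests
therefore demonstrate the statistical machinery is correct under known
ground truth, not that any particular hospital's data behaves this way.

## Discrimination

AUROC uses average ranks (Mann–Whitney; ties half-credited) and is tested
against exhaustive pair counting. AUPRC is average precision with step
interpolation over distinct-score thresholds (matching the standard
implementation convention); it is reported but never compared across
periods, being strongly prevalence-dependent. Standard errors use the
Hanley–McNeil closed form; cross-period tests use the independent-samples
Z — periods contain disjoint stays, so no pairing (DeLong-style covariance)
exists.

**Known conservatism.** The Hanley–McNeil variance assumes a
negative-exponential ROC model. For binormal data it overestimates the true
sampling SD, increasingly so at high AUROC and class imbalance: at the
default conditions (A≈0.92, incidence 0.15, n=2,000/period) the ratio of
the HM SE to the empirical SD is ≈1.36, and the nominal 5% Z-test rejects
under the null at ≈0.8%. Monitoring conclusions of "no significant AUROC
difference" are therefore conservative in this regime; the test will not
over-alarm, but it is under-powered against small discrimination drifts.

Yearly summary convention: yearly percentage metrics are reported as mean
(SD) with the mean rounded half-up to two decimals and the *population* SD
(denominator $n$, since the periods observed are the whole population under
review, not a sample) truncated at two decimals. This is the convention
that exactly reproduces the package's reference summary tables.

## Calibration

Platt scaling is fitted in its original parameterisation
$p = (1 + e^{Af+B})^{-1}$ on $f = \mathrm{logit}(\text{raw})$, by Newton
iterations from the identity $(-1, 0)$ to gradient max-norm $<10^{-8}$ —
the two-parameter problem is strictly convex, and starting at the identity
makes the fit a perturbation analysis of the deployed model. Platt's
Bayes-smoothed targets are available behind a flag but off by default: at
calibration-split sizes in the thousands the smoothing only biases the
recovered offset. The fit uses the calibration split exclusively; test
periods never touch it.

Reliability curves use quantile binning (equal counts per bin, sizes
differing by at most one; stable sort on (probability, position) so ties
split deterministically), which keeps per-bin binomial noise uniform across
the probability range. Per-bin 95% CIs are Wilson intervals, chosen for
small-bin behaviour. ECE and MCE are computed on the same bins as the
plotted curve, so the numbers always describe the curve shown. Ten bins by
default; both bin count and CI method are configuration, not claims.

The shift flag compares each period's post-calibration ECE with the
calibration split's own post-calibration ECE and fires beyond an absolute
margin of 0.05 (configurable). The margin is the package's numeric
replacement for a judgement that is usually made visually; at the default
cohort sizes the null spread of period ECE around the benchmark is well
below 0.02, while a one-logit offset drift exceeds the margin reliably.

*Calibration-split contamination caveat.* The simulator assigns the
calibration split uniformly at random across periods, so drift injected
into a period also leaks into the calibration split (proportional to that
period's share), pulling the Platt fit toward the drift and shrinking the
measured gap. With 4 periods × 20,000 cases and a one-logit final-period
drift the flag fires robustly; with few, small periods (e.g. 3 × 10,000)
the contaminated benchmark can absorb the drift below the 0.05 margin. In
production monitoring the calibration split should predate deployment, in
which case this leakage does not arise.

## Decision impact

The operating threshold minimises $|\mathrm{FNR} - \mathrm{FPR}|$ over the
candidate set of observed distinct probabilities plus {0, 1} — the
objective is piecewise constant between observed values, so the grid is
lossless; ties break toward the smallest threshold (more sensitive
alerting). Alerting is `prob >= threshold`. The five alert categories (TN,
FP, FN, TP, TP-after-onset) acknowledge that an alert on a true case after
onset is diagnostic rather than predictive; because discharge-code labels
carry no onset time, rate computations collapse TP-after-onset into TP and
score an alert at any time during the stay.

Net benefit is $TP/N - (FP/N) \cdot p_t/(1-p_t)$; treat-all equals
$\pi - (1-\pi)p_t/(1-p_t)$ (crossing zero exactly at prevalence), treat-none
is zero. Because a decision curve starts at the period's prevalence,
cross-period comparisons first standardise incidence: every lower-incidence
period is augmented by duplicating positives sampled with replacement, with
the duplicate count minimising the absolute gap to the maximum period
incidence (ties toward fewer duplicates). Duplication — rather than
synthesising cases or reweighting — keeps every score an observed score.

The cross-period comparison is an unpaired case-level bootstrap: resample
within each period independently, recompute both net benefits at each
threshold of interest, and report the two-sided percentile p-value
$2\min(\Pr(\Delta\le 0), \Pr(\Delta\ge 0))$. A percentile bootstrap was
chosen as the nonparametric test because net benefit is a non-smooth
functional of the empirical distribution with no usable closed-form
variance at arbitrary thresholds. Measured type-I error is ≈5% per
threshold (null study at n=600/split, 200 bootstrap replicates, 1,000
replicate studies). Default thresholds of interest are
{0.01, 0.02, 0.05, 0.10, 0.15, 0.20} — the low range where inpatient
alerting operates — and no multiplicity correction is applied by default,
matching how per-threshold monitoring results are conventionally read.

## Pipeline

`run_monitoring` executes profile → Platt fit → threshold selection →
discrimination + Z-tests → calibration report → confusion/decision curves →
incidence standardisation → pairwise curve comparisons, in that order, with
the calibration split isolated from every per-period test metric. All
randomness (split assignment, standardisation, bootstrap) derives from the
single config seed via a seed sequence, making reports byte-identical
across runs; outputs are written only after every stage succeeds.

## Problem sizes used in validation

Parameter-recovery runs use 50,000-case fits (binomial noise well below the
±0.05 recovery tolerance); generator fidelity checks use 50,000–100,000
cases; null studies use 1,000 replicates at 2,000 cases/period (Z-test) and
100 runs at 5,000 cases/period with 1,000 bootstrap replicates
(decision-curve comparison). These sizes put Monte-Carlo error comfortably
inside each stated tolerance while keeping the full validation suite in the
minutes range on a single CPU.

## Known limitations

* The binormal score family is an explicit stand-in; real model scores need
  not be logit-affine distortions of a logistic posterior, so Platt
  recovery being exact here does not imply Platt scaling suffices for any
  deployed model (isotonic or temperature scaling are out of scope by
  design).
* The Hanley–McNeil Z-test's conservatism at high AUROC / low incidence
  (above) is a property of the method, inherited deliberately.
* The bootstrap curve comparison is unpaired; it cannot exploit common-case
  correlation and is mildly conservative when periods share structure.
* The shift flag is a single-number summary (ECE gap); localised
  miscalibration confined to a thin probability range can hide below the
  margin while being visible in the reliability curve itself.
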