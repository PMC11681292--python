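"""Detect a calibration shift that AUROC monitoring cannot see.

A one-logit overestimation offset is injected into the final period only.
Because the distortion is strictly monotone, every period's AUROC is
unchanged — but the final period's post-calibration ECE jumps and the shift
flag fires.
"""

from shiftmon import CohortConfig, auroc, calibration_shift_report, generate_cohort

cohort = generate_cohort(
    CohortConfig(n_per_period=20_000, miscal_offset=(0.0, 0.0, 0.0, 1.0), seed=7)
)
report = calibration_shift_report(cohort, n_bins=10, margin=0.05)

print(f"calibration-split ECE after Platt scaling: {report.reference_calibrated.ece:.4f}\n")
for period, entry in report.periods.items():
    split = cohort.test(period)
    a = auroc(split["raw_score"], split["label"])
    flag = "  <-- CALIBRATION SHIFT" if entry.shift_flag else ""
    print(
        f"{period}: AUROC {a:.4f} | ECE raw {entry.raw_errors.ece:.4f} -> "
        f"calibrated {entry.calibrated_errors.ece:.4f} | "
        f"MCE calibrated {entry.calibrated_errors.mce:.4f}{flag}"
    )
print(
    "\nThe drifted period keeps an AUROC indistinguishable from the clean"
    "\nperiods (the distortion preserves ranking) while its ECE exceeds the"
    "\ncalibration-split benchmark by more than the 0.05 margin."
)
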