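"""Run the full relapse-pattern analysis on a synthetic 13-case cohort.

Generates paired baseline/relapse phantoms (cavity shrinking ~12 ml and
shifting ~6 mm, relapse lesion only partly inside the baseline lesion),
then runs segmentation, overlap analysis, target-volume simulation,
recurrence classification and the paired tests in one call.
"""

from fetrelapse import PhantomConfig, generate_cohort, run_cohort

cohort = generate_cohort(PhantomConfig(), n_cases=13, seed=11)
report = run_cohort([case for case, _ in cohort])

ov = report.summaries["overlap"]
print(f"baseline FET volume, median : {ov['fet1_ml']['median']:.1f} ml")
print(f"baseline FET∩MRI overlap    : {ov['intersect1_pct_of_fet1']['median']:.1f} %")
cav = report.summaries["cavity"]
print(f"cavity shift, mean          : {cav['shift_mm']['mean']:.1f} mm")
print(f"cavity shrinkage, mean      : {cav['shrinkage_ml']['mean']:.1f} ml")
cov = report.summaries["coverage_matrix"]
for margin in (0, 5, 7, 10):
    fet = cov[f"coverage_FET_{margin}mm"]["median"]
    mri = cov[f"coverage_MRI_{margin}mm"]["median"]
    print(f"relapse coverage at {margin:2d} mm  : FET {fet:.2f} vs MRI {mri:.2f}")
p = report.wilcoxon["ptv2_vs_fet_plus7_volume"]["p_two_sided"]
print(f"PTV-2 vs FET+7mm PTV volume : exact Wilcoxon p = {p:.2g}")
print(f"recurrence labels           : {sorted(set(report.recurrence_labels.values()))}")

# Coverage rises monotonically with margin and is higher for FET-based than
# MRI-based target volumes; the FET-based PTV is significantly smaller than
# the standard MRI-based PTV-2 on the same cohort.
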