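# fetrelapse

Relapse-pattern analysis and radiation target-volume simulation for
amino-acid-PET-guided radiotherapy of glioblastoma.

After resection of a glioblastoma, radiotherapy target volumes are usually
drawn on contrast-enhanced MRI — but gadolinium enhancement marks
blood-brain-barrier disruption, not metabolically active tumor. FET-PET
(O-(2-¹⁸F-fluoroethyl)-L-tyrosine) delineates active tumor directly: the
*biological target volume* is autocontoured as all voxels with a
tumor-to-brain ratio TBR ≥ 1.6, where TBR is voxel uptake divided by the
mean uptake of a normal-brain reference region. This package implements,
as a tested library, the full analysis used to study where glioblastomas
recur relative to such FET-based boost volumes and how an optimal margin
would look:

- **Segmentation** — TBR computation and threshold autocontouring of PET;
  threshold delineation of MRI enhancement.
- **Geometry** — isotropic margin expansion (Euclidean distance transform,
  anisotropy-aware) building CTVs and PTVs (CTV = tumor + microscopic-spread
  margin; PTV = CTV + 5 mm setup margin); volume, intersection, and
  coverage metrics; resection-cavity shrinkage (ml) and shift (mm).
- **Phantoms** — seeded synthetic paired baseline/relapse brain phantoms
  with exact ground truth, emulating the cohort's structure (cavity
  shrinking ~12 ml and shifting ~6 mm; MRI enhancement overlapping ~12 %
  of the FET volume; the relapse lesion only ~39 % inside the baseline
  lesion).
- **Pipeline** — per-case and cohort orchestration: FET/MRI overlap at
  both time points, recurrence coverage by the delivered boost PTV-1 and
  standard PTV-2, a simulated margin ladder (0/5/7/10 mm) from FET- and
  MRI-based baseline volumes, and local/distant recurrence classification.
- **Statistics & fixtures** — exact two-sided Wilcoxon signed-rank test
  (zeros dropped, midrank ties, full sign-assignment null distribution)
  and the published 13-patient cohort tables packaged as
  transcription-checksummed CSV fixtures.

## Worked example

```python
from fetrelapse import PhantomConfig, generate_cohort, run_cohort

cohort = generate_cohort(PhantomConfig(), n_cases=13, seed=11)
report = run_cohort([case for case, _ in cohort])

cav = report.summaries["cavity"]
print(f"cavity shift, mean     : {cav['shift_mm']['mean']:.1f} mm")
print(f"cavity shrinkage, mean : {cav['shrinkage_ml']['mean']:.1f} ml")
cov = report.summaries["coverage_matrix"]
for margin in (0, 5, 7, 10):
    print(f"coverage at {margin:2d} mm     : "
          f"FET {cov[f'coverage_FET_{margin}mm']['median']:.2f} "
          f"vs MRI {cov[f'coverage_MRI_{margin}mm']['median']:.2f}")
print(f"PTV-2 vs FET+7mm PTV   : p = "
      f"{report.wilcoxon['ptv2_vs_fet_plus7_volume']['p_two_sided']:.2g}")
```

prints

```
cavity shift, mean     : 6.1 mm
cavity shrinkage, mean : 12.8 ml
coverage at  0 mm     : FET 0.38 vs MRI 0.28
coverage at  5 mm     : FET 0.69 vs MRI 0.68
coverage at  7 mm     : FET 0.80 vs MRI 0.80
coverage at 10 mm     : FET 0.95 vs MRI 0.96
PTV-2 vs FET+7mm PTV   : p = 0.00024
```

Reading: across 13 synthetic cases the resection cavity moved ~6 mm and
lost ~13 ml between baseline and relapse; coverage of the recurrent FET
volume rises monotonically with the simulated margin; and the FET-based
PTV (7 mm margin + 5 mm setup) is significantly smaller than the standard
MRI-based PTV-2 under the exact paired signed-rank test. The
`examples/` directory has one short script per capability
(segmentation, target-volume ladders, cohort analysis, fixture-table
reproduction), and the same functionality is scriptable via the
`fetrelapse` command (`segment`, `simulate-targets`, `make-phantom`,
`run`, `paper-tables`).

On the *published* cohort fixtures (`fetrelapse.reproduce_paper_summaries()`),
the recomputed medians give the study's headline numbers: baseline FET and
MRI volumes 9.1 vs 4.9 ml, FET∩MRI overlap 12.1 % at baseline and 13.3 %
at relapse, 38.9 % of the recurrent volume inside the delivered boost
PTV-1 but 100 % inside the standard PTV-2, simulated 7 mm FET-based CTV
coverage 100 % vs 85 % for MRI, and a 7 mm FET-based PTV of 160 ml vs the
231 ml standard PTV-2 (exact Wilcoxon p = 4.9·10⁻⁴).

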