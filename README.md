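# lgequant

Semi-automated quantification of myocardial scar on late-gadolinium-
enhancement (LGE) cardiac MR, and the statistics needed to compare
quantification methods against reference planimetry.

Focal fibrosis appears bright on post-contrast T1-weighted short-axis
images. Standard practice classifies a myocardial pixel as scar when its
signal intensity exceeds either `mu + n*sigma` (remote-myocardium mean plus
n standard deviations, n = 2, 3, 5) or half the maximal signal of the
hyperenhanced region (FWHM); burden is reported as grams and as
`(M_LGE / M_M) x 100` percent of LV mass. For the small intramural striae
seen in arrhythmic mitral-valve-prolapse patients, these rules disagree
several-fold: partial-volume pixels at the scar border sit far above a 2-SD
cut but below a 5-SD cut. `lgequant` implements the full measurement
protocol (remote-ROI statistics over three consecutive slices with >= 100
pixels each, volume-wide thresholding, papillary/blood exclusion, mass
conversion at 1.05 g/ml), a synthetic short-axis phantom cohort with known
ground-truth scar, a parametric observer model for re-read experiments, and
the agreement battery: Bland–Altman bias with 1.96-SD limits, ICC(A,1)
absolute agreement with the >= 0.9 optimal-concordance rule, paired
Wilcoxon, and chi-squared/Fisher and t/Mann–Whitney group tests.

See `docs/methods.md` for the model details and pinned conventions.

## Worked example

```python
from lgequant import (CohortSpec, ObserverModel, run_study)

tables = run_study(CohortSpec(seed=1), inter_subset_n=16)
t2 = tables.table2.query("unit == 'percent'")
print(t2[["method", "mean", "sd"]].to_string(index=False))
```

```
method     mean       sd
visual 2.301150 0.575221
  fwhm 2.432939 0.589728
   sd2 4.942309 0.768985
   sd3 2.710949 0.616859
   sd5 2.402864 0.581033
```

A 66-subject synthetic cohort (41 scar-positive) quantified by all five
methods: the 2-SD threshold measures roughly twice the planimetry burden
(border pixels and noise false positives), 3-SD still overestimates, FWHM
sits closer, and 5-SD lands nearest the reference — the characteristic
ordering for small, soft-edged scar. `tables.table5` gives the
corresponding Bland–Altman biases vs planimetry (here +2.64, +0.41, +0.13,
+0.10 percentage points for sd2/sd3/fwhm/sd5), `tables.table3` the intra-
and inter-observer ICCs from the simulated re-reads, and `tables.table4`
the paired Wilcoxon tests.

The same machinery is scriptable from the shell:

```sh
lgequant phantom --spec spec.yaml --out subject_dir/
lgequant cohort  --spec cohort.yaml --out cohort_dir/
lgequant quantify --image img.nii.gz --myo-mask myo.nii.gz \
    --method sd5 --remote-roi rois.yaml --out result.json
lgequant study --cohort cohort.yaml --out tables_dir/
```

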