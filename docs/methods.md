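# Methods

## Problem and scope

`lgequant` implements the comparison of semi-automated late-gadolinium-
enhancement (LGE) quantification techniques on short-axis cardiac MR:
gray-scale thresholds at 2, 3 and 5 standard deviations above remote
myocardium, the full-width-at-half-maximum (FWHM) rule, and manual
planimetry as the reference. The clinical target phenotype is the small
intramural/subepicardial fibrosis stria of the basal–mid inferolateral wall
seen in arrhythmic mitral-valve-prolapse patients: scar burdens of a few
percent of LV mass, where the choice of threshold changes the measured
burden several-fold. Because no raw patient images are available, the
package ships a synthetic phantom cohort with known ground truth; all
empirical claims in the test suite are claims about these phantoms.

## Quantification model

For each subject, remote (visually normal) myocardium is sampled with
circular ROIs on three consecutive short-axis slices, each retaining at
least 100 myocardial pixels. Per-slice means and population SDs are
combined by plain averaging into a reference mean `mu` and SD `sigma`
(pooled SD is available as an option; the averaged form is the default
protocol). Thresholds:

* n-SD: `mu + n * sigma`, n in {2, 3, 5};
* FWHM: `0.5 * max(SI)` inside a reader-placed hyperenhancement ROI
  (an upper-percentile variant is available to tame hot pixels).

A single threshold per subject is applied volume-wide with a strict `>`
comparator and no connectivity filtering (an optional minimum-cluster
filter exists but is off by default). LGE and myocardial masses use
`mass_g = count * pixel^2 * (thickness + gap) / 1000 * 1.05`, with
1.05 g/ml the standard myocardial density (configurable; through-plane
voxel extent is thickness + gap, gap defaulting to 0). Burden is reported
as `(M_LGE / M_M) * 100`. The myocardial mask includes scar (scar is wall
tissue) and excludes papillary muscles and blood pool. LGE presence
requires visibility in at least two orthogonal views (`lge_present`);
in the synthetic pipeline presence is taken from ground truth, since
phantoms are single-orientation.

## Phantom model

Each slice is a circular annulus (myocardium, intensity 50 by default)
around a bright blood pool (150) with two papillary-muscle cylinders,
rendered on a 96x96 grid at 1 mm pixels, 8 slices of 8 mm. The scar is an
annulus sector: angular position/extent, radial transmurality and wall
position (intramural / subepicardial / subendocardial) are parameters.
Angles run clockwise from the anterior wall (0 deg); the inferolateral
default is 240 deg. An intramural sector centred on the mid radius covers
exactly the transmurality fraction of the annulus area, which gives the
closed-form oracle used in the tests.

Partial volume is modelled as a linear intensity ramp of width
`edge_softness_px` across the scar boundary (an approximate signed distance
combining radial and arc components); the ground-truth label cuts the ramp
at weight 0.5. This ramp is what makes low thresholds overcount: an n-SD
threshold cuts the ramp at weight `(n*sigma) / (core - mu)` rather than
0.5. Noise is iid Gaussian per voxel (default) or Rician (magnitude of a
complex signal with two Gaussian channels); Gaussian is the default because
it keeps the analytic checks exact, and the Rician positive bias at
moderate SNR is asserted by sign only. Intensities are clipped at zero.
Determinism: everything derives from integer seeds via `SeedSequence`;
per-subject seeds are stable hashes of (cohort seed, index).

### Default cohort calibration

The default `CohortSpec` (66 subjects, prevalence 41/66) draws scar extent
U(40, 70) deg, transmurality U(0.35, 0.60), 2–3 scar slices starting in the
basal–mid stack, noise sigma U(8, 12), edge softness U(0.8, 1.5) px, and a
scar-core contrast of U(11, 14) remote SDs. The contrast range is the load-
bearing choice: with core `= mu + c*sigma`, the FWHM threshold
`0.5*(mu + c*sigma)` cuts the partial-volume ramp at weight `0.5 - mu/(2c
sigma)`, which (at the default mu = 50, sigma ~ 10) lies between the 3-SD
cut (`3/c`) and the 5-SD cut (`5/c`) exactly for c in (11, 15) — so the
mean-burden ordering sd2 > sd3 > fwhm > sd5 ~ visual and the bias ordering
|sd5| < |fwhm| < |sd3| < |sd2| emerge from the geometry rather than from
per-method adjustments. Scar-size ranges were set once so the 5-SD mean
burden lands near ~2.4% of LV mass, the regime of interest for small-burden
fibrosis. The synthetic cohort does not emulate coil-sensitivity bias
fields, motion, spatially correlated noise or through-plane prolapse
geometry; conclusions from passing tests are about threshold arithmetic,
partial volume and iid noise, not about those effects.

## Observer model

Re-reads perturb only what a reader controls: ROI centres slide along the
wall (arc displacement ~ N(0, jitter)) with a radially clamped offset so
the ROI keeps its minimum pixel count, and the planimetry boundary shifts
per slice by a signed-distance offset ~ N(0, sd_px) (dilation/erosion via
Euclidean distance transforms), giving correlated over/under-segmentation.
A zero-noise observer reproduces the primary read bit-for-bit, so ICCs are
exactly 1 — the anchor of the variability experiment. Default re-reader
settings (intra: 1.5 px ROI jitter, 0.5 px boundary SD; inter: 2.5 px and
0.6 px) were chosen so that a boundary re-draw moves a slice contour by a
full pixel on roughly 5–10% of slices; because a 1-px shift changes a thin
stria's area by tens of percent, larger values are unrealistically noisy.
The per-slice offset is effectively quantised to whole-pixel shifts, which
is deliberate: planimetry differences are redrawn contours, not per-pixel
salt noise. Scar-free subjects get an empty visual mask and a zero FWHM
result (the FWHM protocol presupposes a hyperenhanced region to seed its
ROI); their n-SD arms are quantified normally and measure the noise floor.

## Statistics

* Descriptives: mean, sample SD, median and quartiles (type-7 linear
  interpolation — pinned because these feed tables).
* Bland–Altman: differences are method minus reference (reference second);
  limits are bias ± 1.96 x sample SD of the differences.
* ICC: two-way random-effects, absolute agreement, single measurement —
  ICC(A,1) = (MS_S − MS_E) / (MS_S + (k−1)MS_E + (k/n)(MS_R − MS_E)) from
  explicit two-way mean squares; the residual sum is computed elementwise
  so identical raters give exactly 1.0. ICC(A,k) is available via
  `form="average"`. Labels: optimal ≥ 0.9, good ≥ 0.8, else sub-optimal.
* Paired Wilcoxon: zeros discarded (classic, not Pratt), mid-ranks for
  ties; exact two-sided p for ≤ 25 nonzero pairs by counting over the
  doubled-rank distribution (equivalent to full sign enumeration, which the
  tests verify), otherwise a normal approximation with tie and continuity
  corrections. Type-I error at n = 41 calibrates to the nominal 5%.
* Two-group tests: chi-squared without continuity correction, switching to
  Fisher's exact when any expected cell < 5; Student's t when both groups
  pass a Shapiro screen at alpha 0.05, else Mann–Whitney U.

## Study pipeline and problem sizes

`run_study` quantifies every LGE-positive subject under a primary read, an
intra-observer re-read (all positives) and an inter-observer re-read (first
16 positives), then emits: per-method summaries of percent and grams over
positives only; intra-/inter-observer ICCs; paired Wilcoxon of each
semi-automated method against planimetry; and Bland–Altman agreement
against planimetry. A manifest (cohort spec, observer parameters, version)
allows bit-identical reruns. The shipped experiment sizes — a 66-subject
cohort, 20-seed sweeps for the ordering and monotonicity properties, 2000
replicates for Wilcoxon calibration — run the full suite in well under a
minute on one core.

## Known limitations

* A hard threshold against a plateau close to it loses voxels one-sidedly:
  at plateau contrast `c*sigma`, the expected retained plateau fraction is
  `Phi(c − n)`. At c = 6 the 5-SD method therefore under-measures by at
  least ~16% in expectation regardless of noise level, and partial-volume
  ramps add further loss; recovery within a few percent (as the default
  cohort shows, mean |relative error| ~5%) requires the higher contrasts
  typical of nulled-myocardium LGE.
* The observer model is a two-parameter caricature; its ICCs should be read
  as controllable experiment dials, not predictions of human reader
  variability.
* Real-data mode expects pre-traced myocardial masks; no automatic
  segmentation, sub-pixel contours, DICOM series assembly, or AHA-segment
  reporting.
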