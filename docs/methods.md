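# Methods

## The quantification model

The pipeline quantifies myocardial fibroblast-activation PET the way a
clinical workstation would, but with every step explicit and tested.

**SUV conversion.** Body-weight SUV: voxel activity concentration (Bq/mL)
divided by injected dose per gram of body mass. The dose is decay-corrected
with the ⁶⁸Ga half-life (67.71 min) to the acquisition start by default;
sites that correct to injection time can switch via
`SuvCalibration.decay_reference`. Negative reconstructed values are clamped
to zero before any statistic — they are reconstruction artifacts and would
corrupt the across-voxel standard deviation that feeds the threshold.

**Blood-pool reference.** A sphere of default radius 10 mm (user-supplied
center in clinical use; the cavity centroid in the phantom). A voxel
belongs to the sphere iff its center lies within the radius — no
partial-volume weighting. A VOI under 10 voxels is rejected: the threshold
consumes the across-voxel sd, which is meaningless on a handful of voxels.
The sd uses the population (1/n) denominator, treating the VOI as the full
background distribution; the sample (1/(n−1)) convention is a `ddof`
argument away.

**Threshold and EFM.** `Threshold = 1.25·SUVmean(BP) + 1.0·SUVstd(BP)`,
both coefficients configurable (the classical mean + 1·sd background cutoff
is `ThresholdConfig(1.0, 1.0)`). Myocardial voxels strictly above the
threshold form the EFM mask; ties are background. An empty EFM yields
missing (NaN) metrics, never zeros, and propagates as missing downstream.
The threshold is recomputed per time point from that time point's blood
statistics.

**TBR.** `TBR(EFM) = SUVmax(EFM) / SUVmean(BP)`. Two exact invariances are
tested: global rescaling of the volume changes nothing (threshold, mask and
both numerator and denominator scale together), and whenever EFM is
non-empty, SUVmax(EFM) equals SUVmax over the whole myocardium (the maximal
voxel exceeds the threshold iff any voxel does).

**Registration.** Later CT frames are rigidly aligned to the 60-min CT
(SimpleITK Euler transform, mean-squares metric, dense sampling so results
are bit-reproducible, two-level multi-resolution descent). The transform
carries the blood VOI and LV mask to each frame's native grid
(nearest-neighbour, binarity preserved); PET voxels are never interpolated
during quantification. Contractual accuracy on noise-free phantoms: 0.5
voxel translation, 1° rotation; the implementation achieves ~0.1 mm / 0.1°.

**Responder endpoint.** Five criteria with the thresholds in the README;
all are configuration with those defaults. Two design points were genuinely
open and are resolved as follows: (i) conditional criteria (hsCRP if
elevated, LVEF if baseline < 60 %) are excluded from the numerator when
ineligible but the "≥ 2 met" bar is never reduced — a patient with fewer
than two eligible criteria cannot be a responder; (ii) "elevated" hsCRP is
undefined upstream, so the default cutoff is 5 mg/L (0.5 mg/dL),
configurable, and the hsCRP unit (mg/L vs mg/dL, both in circulation) is a
required field rather than an assumption. Patients without follow-up are
excluded from outcome analysis, never imputed or classified.

**Statistics.** Time stability uses repeated-measures ANOVA on balanced
series and a linear mixed model with subject random intercepts (Wald test
on the time terms) when scans are missing; a metric exactly constant within
every subject short-circuits to p = 1 (the F statistic is 0/0 there).
Associations: Pearson (optionally on log NT-proBNP, which is right-skewed
over more than an order of magnitude; raw-scale Spearman is always emitted
alongside) plus an OLS fit with CI. Group comparisons: Student t with a
Shapiro–Wilk gate at α = 0.05, falling back to Mann–Whitney; the
Mann–Whitney p is exact by full rank-assignment enumeration over midranks
for groups ≤ 10 (the regime of an 11-patient follow-up cohort; midranks
make fully tied data give p = 1 and handle ties without approximation),
and the tie-corrected normal approximation above that. Change-from-baseline
effects use OLS ANCOVA adjusting for the baseline covariate, with a
collinearity guard. Post-hoc pairwise time comparisons are
Bonferroni-corrected within the three-time-point family.

## The phantom

The phantom is deliberately geometric: an ellipsoidal myocardial shell
(outer semi-axes 42/34/34 mm, inner 30/22/22 mm on a 64³ grid of 3 mm
voxels) around a blood-filled cavity, with spherical high-uptake lesions
embedded in the wall. That is sufficient to exercise masking, thresholding,
registration and statistics against exact ground truth; it is **not** an
anatomical heart — no papillary muscles, wall-thickness variation, motion
blur or spillover.

Uptake levels at 60 min follow the cohort means of severe-AS patients:
blood 3.2, remote myocardium 2.2, lesion 7.0 (giving true TBR 7.0/3.2 ≈
2.2). Kinetics are mono-exponential per compartment from 60 min; the
default uses one shared clearance rate λ = ln(3.2/1.8)/60 min⁻¹ for both
compartments (half-time ≈ 72.3 min), which reproduces blood 3.2 → 1.8 and
myocardial EFM 3.8 → 2.1 at the precision those means are quoted — i.e.
the reported washout is proportional, which is exactly what makes TBR
time-robust. Per-compartment half-times are configurable; the
configuration refuses blood clearing slower than myocardium, since the
tracer's behavior is rapid blood clearance with retained tissue binding.

Noise is Gaussian on SUV with sd equal to a fraction (default 10 %) of the
local noise-free value, clamped at zero — a reconstruction-domain
approximation appropriate because the pipeline consumes reconstructed SUV
images, not count data. No PSF, attenuation, scatter or cardiac/respiratory
motion is simulated. Within-patient noise correlation across time points is
unknown in real data and is therefore a generator parameter, not an assumed
value.

The CT-like channel adds fixed high-density landmarks (a spine-like column,
a sternal plate, an apical marker) outside and on the shell. A bare
ellipsoid is nearly rotation-symmetric, which makes rigid registration
ill-conditioned in rotation; real thoraxes are not symmetric, and the
landmarks restore that conditioning.

Patient repositioning between acquisitions is simulated by sampling the
rigidly moved anatomy on the scanner grid with fresh voxel noise — not by
interpolating an existing frame. Interpolation would smooth the noise of
later frames only, systematically deflating their SUVmax and manufacturing
a spurious TBR time effect.

## The synthetic cohort

Two layers. The voxel layer gives every patient a phantom whose lesion
intensity encodes a true TBR drawn from the study's group calibration:
responders 1.7 ± 0.2, non-responders 2.9 ± 0.9, remainder 2.2 ± 0.8, with
a floor at 1.45 so every lesion stays detectable above the blood-anchored
threshold (the floor shifts the generated group difference by ≈ +0.06,
accounted for in the generator's own recovery test). Baseline NT-proBNP is
log-linear in TBR (log NT = 4.6 + 1.0·TBR + ε, ε ~ N(0, 1.05)), chosen so
the baseline correlation is ≈ 0.65 and the NT-proBNP range spans ~130–4800
pg/mL. Follow-up covariates are constructed so the ground-truth label
provably satisfies the composite rule (responders always meet criteria a
and b with NT-proBNP drops of 45–65 %; non-responders stay below every
threshold except an occasional single NYHA class, and two of them have
rising NT-proBNP). Cohort structure mirrors the study: 19 patients, 11
with follow-up (5 responders / 6 non-responders), 2 missing the 120-min
scan.

The summary layer (`generate_metric_timeseries`) simulates per-patient TBR
and SUVmean trajectories directly, with between-patient sds of 0.8 / 0.7
and within-patient measurement noise of 0.15 / 0.30 SUV — plausible
test–retest magnitudes; the true within-patient value is unreported, so it
is a parameter. This layer powers the Monte-Carlo studies of the
time-stability statistics (200 replicates × 100 patients) where voxel
phantoms would be needlessly slow.

## Numerical and scale choices

Problem sizes were chosen for desk-scale runtime: 64³ voxels at 3 mm, a
19-patient demo (~20 s end-to-end), 100–200 Monte-Carlo replicates at the
summary layer, 1000 replicates for type-I calibration, and exhaustive
enumeration wherever the space is small (243 responder states, C(n₁+n₂,n₁)
rank assignments). Registration uses a two-level pyramid (shrink 4/2) with
≤ 100 iterations — sufficient for ~0.1 mm accuracy on these phantoms.
All randomness flows from explicit integer seeds; identical seeds give
bit-identical volumes, tables and reports.

## Known limitations and honest readings

Measured TBR exceeds its ground-truth value by the noise inflation of the
maximum statistic (≈ +0.3 at 10 % noise on this geometry, vanishing as
noise → 0 — a tested property). Real SUVmax carries the same bias, so the
phantom is faithful in kind, but cohort means measured here should not be
read as estimates of any particular clinical cohort's printed values.
Relatedly, a published EFM SUVmean of 3.8 alongside blood SUVmean 3.2 is
arithmetically incompatible with a 1.25·mean + sd threshold (which would
sit at ≥ 4.0); those figures are consistent only with the mean + 1·sd
variant, which is why both remain one configuration apart here. Passing
tests demonstrate correctness of the pipeline's arithmetic, invariances
and statistical calibration under the generator's assumptions — not
clinical performance on patient data, which involves anatomy, motion and
reconstruction effects the phantom deliberately omits.
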