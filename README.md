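# fapitbr

Quantification pipeline for myocardial [⁶⁸Ga]Ga-FAPI PET in aortic
stenosis: blood-pool–anchored segmentation of elevated fibroblast-activity
myocardium (EFM), the time-robust myocardium-to-blood ratio TBR(EFM),
multi-time-point rigid co-registration, a composite one-year post-TAVI
responder endpoint, and the accompanying cohort statistics — all exercised
end-to-end on synthetic cardiac phantoms with known ground truth.

## Who this is for

Nuclear-medicine and cardiac-imaging researchers who want a tested,
reproducible implementation of blood-pool–normalized FAPI quantification:
either to analyze their own SUV volumes and LV masks (NIfTI in, CSV/JSON
out), or to study the method's statistical behavior on simulated cohorts
before committing scanner time.

## The method

For each acquisition time point *t* (60, 70, 120 min post-injection), a
spherical volume of interest in the LV blood pool yields
SUV<sub>mean</sub>(Blood pool) and the across-voxel SUV<sub>std</sub>(Blood
pool). The segmentation threshold is anchored on that background
distribution:

```
Threshold(t) = 1.25 · SUVmean(Blood pool, t) + 1.0 · SUVstd(Blood pool, t)
```

Myocardial voxels with SUV **strictly above** the threshold form the EFM
mask, and the biomarker is

```
TBR(EFM, t) = SUVmax(EFM, t) / SUVmean(Blood pool, t)
```

Because tracer clears proportionally from blood and myocardium beyond
~60 min, TBR is invariant to acquisition time while raw SUV is not, and it
is exactly invariant to global rescaling of the image (dose, calibration).
The 70- and 120-min frames are rigidly registered to the 60-min CT; the
blood VOI and LV mask are carried through the transform and all statistics
recomputed on each frame's native image.

One-year clinical response is a composite: improvement in ≥ 2 of
(a) NT-proBNP ↓ ≥ 30 %, (b) NYHA ↓ ≥ 1 class, (c) hsCRP ↓ ≥ 15 % if
elevated, (d) dyspnea "much better", (e) LVEF ↑ ≥ 5 points if baseline
< 60 %.

## Worked example

`examples/02_time_robustness.py` quantifies a noise-free phantom at all
three time points:

```
time (min)  blood mean  SUVmean(EFM)  TBR(EFM)
        60       3.200         7.000    2.1875
        70       2.907         6.360    2.1875
       120       1.800         3.938    2.1875
```

Blood SUVmean falls 3.2 → 1.8 between 60 and 120 min and absolute EFM
uptake falls with it (~44 %), but the blood-normalized TBR does not move —
the mechanism that makes a single 60-min acquisition sufficient.

`examples/05_cohort_statistics.py` runs the full 19-patient synthetic
study (two patients missing the 120-min scan, 11 with one-year follow-up)
through simulation, registration, quantification, responder classification
and statistics:

```
TBR time effect (mixed model)      p = 0.678
SUVmean(EFM) time effect           p = 1.99e-101
TBR vs log NT-proBNP (60 min)      r = 0.58, p = 0.009
responders 2.29 vs non-responders 3.83 (Mann-Whitney p = 0.004)
```

TBR shows no time effect while SUVmean's decline is overwhelming; baseline
TBR correlates with log NT-proBNP; and responders sit well below
non-responders, separated by the exact Mann–Whitney test. (Measured TBR
runs slightly above its ground-truth value because SUVmax is a maximum
over noisy voxels; see `docs/methods.md`.)

The other examples cover single-scan quantification, registration/VOI
propagation accuracy, and the responder rule on hand-built patients. A
thin CLI exposes each stage (`fapitbr simulate | quantify | classify |
stats | demo`), re-runnable from files.

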