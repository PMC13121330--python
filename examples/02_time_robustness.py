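"""Why TBR is time-robust while SUV is not.

Generates a noise-free phantom at 60/70/120 min with proportional
myocardial/blood washout (the default calibration: blood SUVmean 3.2 ->
1.8), quantifies each time point and prints the series: absolute uptake
falls by ~45% while the blood-normalized TBR stays constant.
"""

from fapitbr import (
    KineticsConfig,
    PhantomConfig,
    compute_threshold,
    efm_metrics,
    extract_efm,
    generate_phantom,
)
from fapitbr.voi import blood_pool_stats

result = generate_phantom(PhantomConfig(noise_sd_frac=0.0, seed=1), KineticsConfig())

print(f"{'time (min)':>10} {'blood mean':>11} {'SUVmean(EFM)':>13} {'TBR(EFM)':>9}")
for t in (60.0, 70.0, 120.0):
    vol = result.suv[t]
    bp = blood_pool_stats(vol, result.truth.blood_voi, time_min=t)
    thr = compute_threshold(bp)
    efm = extract_efm(vol, result.truth.myo_mask, thr)
    m = efm_metrics(vol, efm, bp, threshold=thr, time_min=t)
    print(f"{t:>10.0f} {bp.suv_mean:>11.3f} {m.suv_mean:>13.3f} {m.tbr:>9.4f}")

print()
print("Blood and myocardium clear at the same relative rate beyond 60 min,")
print("so their ratio (TBR) is invariant; raw SUV depends on acquisition time.")
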