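"""Quantify a single synthetic cardiac scan.

Builds one noisy phantom (ellipsoidal LV shell, blood-filled cavity, one
focal high-uptake lesion), places the spherical blood-pool VOI, computes
the blood-anchored threshold, extracts the elevated-uptake myocardium
(EFM) and prints the resulting metrics next to the ground truth.
"""

from fapitbr import (
    PhantomConfig,
    KineticsConfig,
    compute_threshold,
    efm_metrics,
    extract_efm,
    generate_phantom,
)
from fapitbr.voi import blood_pool_stats

result = generate_phantom(PhantomConfig(seed=7), KineticsConfig(times_min=(60.0,)))
vol = result.suv[60.0]

bp = blood_pool_stats(vol, result.truth.blood_voi, time_min=60.0)
threshold = compute_threshold(bp)
efm_mask = extract_efm(vol, result.truth.myo_mask, threshold)
m = efm_metrics(vol, efm_mask, bp, threshold=threshold, time_min=60.0)

print(f"blood pool: SUVmean {bp.suv_mean:.3f}, SUVstd {bp.suv_std:.3f} ({bp.n_voxels} voxels)")
print(f"threshold = 1.25*mean + 1.0*sd = {threshold:.3f} SUV")
print(f"EFM: {m.n_voxels} voxels ({m.volume_ml:.1f} mL), SUVmean {m.suv_mean:.2f}, SUVmax {m.suv_max:.2f}")
print(f"TBR(EFM) measured {m.tbr:.3f} vs ground truth {result.truth.tbr[60.0]:.3f}")
print()
print("TBR is SUVmax(EFM)/SUVmean(blood); the small excess over truth is the")
print("noise inflation of the maximum statistic, which vanishes as noise -> 0.")
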