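"""Individualized segmentation threshold from healthy-liver background SUVmax.

Simulates a noisy torso phantom (liver background SUV 2.97), measures SUVmax
in three 25 cc spherical ROIs inside the healthy liver, extends to five ROIs
if the three disagree by 0.1-0.2 SUV, and averages the retained values into
the patient-specific threshold tau. Every voxel with SUV strictly above tau
is treated as tumour.
"""

import gatedpet as gp

spec = gp.torso_preset("torso16", noise="gaussian_sqrt", seed=7)
phantom = gp.simulate_gated(spec)

est = gp.estimate_threshold(
    phantom.series[0], phantom.healthy_liver_mask, roi_volume_cc=25.0, seed=7
)

print(f"ROI SUVmax measurements : {[round(v, 3) for v in est.roi_suvmax]}")
print(f"spread                  : {est.spread:.3f} SUV ({est.n_rois} ROIs used)")
print(f"threshold tau           : {est.threshold:.3f} SUV")
print()
print("The threshold sits above the true background (2.97) because the")
print("SUVmax of a noisy ROI overshoots the mean — exactly the behaviour the")
print("clinical protocol measures. Three ROIs suffice when they agree within")
print("0.1 SUV; five are used when they agree within 0.2.")
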