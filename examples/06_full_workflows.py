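"""Gated vs conventional planning workflow on one simulated exam.

Runs both planning chains on a moving-lesion phantom: the gated workflow
(threshold from the reference phase -> per-phase BTVs -> BITV -> +3 mm
isotropic -> PTVg) and the conventional workflow (threshold on the
time-averaged exam -> BTV -> CTV -> +5 mm radial / 10 mm craniocaudal ->
PTV), then prints the per-lesion volumes side by side.
"""

import gatedpet as gp

spec = gp.torso_preset("torso16", motion_amplitude_mm=8.0,
                       noise="gaussian_sqrt", seed=3)
phantom = gp.simulate_gated(spec)
nongated = gp.simulate_nongated(phantom.series)
config = gp.PipelineConfig(reference_phase=0, seed=3)

gated = gp.run_gated_workflow(phantom.series, phantom.healthy_liver_mask, config)
conv = gp.run_nongated_workflow(nongated, phantom.liver_mask, config,
                                threshold=gated.threshold.threshold)

gv = next(iter(gated.volumes().values()))
cv = next(iter(conv.volumes().values()))
print(f"threshold tau (reference phase) : {gated.threshold.threshold:.3f} SUV")
print(f"gated        : BITV {gv['bitv_cc']:6.2f} cc -> PTVg {gv['ptvg_cc']:6.2f} cc (+3 mm)")
print(f"conventional : BTV  {cv['btv_cc']:6.2f} cc -> PTV  {cv['ptv_cc']:6.2f} cc (+5/10 mm)")
print()
print("The BITV exceeds the blurred non-gated BTV because it sums the lesion")
print("over the breathing cycle, yet the final gated plan (PTVg) is smaller")
print("than the conventional PTV: the measured excursion replaces the blanket")
print("craniocaudal motion margin.")
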