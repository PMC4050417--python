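"""BITV growth with respiratory motion amplitude.

An 8 cc sphere (SUV 5.6) moves craniocaudally with a sinusoidal excursion.
Each of the six gated phases is thresholded, lesions are matched across
phases, and their union forms the Biological Internal Target Volume (BITV).
With no motion the BITV equals the single-phase BTV; larger excursions sweep
the lesion through more voxels and grow the BITV monotonically.
"""

import gatedpet as gp

geo = gp.GridGeometry((64, 64, 64), (2.0, 2.0, 2.0))
tau = 3.5

print("amplitude (mm)   BITV (cc)")
for amp in (0.0, 5.0, 10.0, 15.0):
    spec = gp.torso_preset("torso8", motion_amplitude_mm=amp, geometry=geo)
    res = gp.simulate_gated(spec)
    sets = gp.segment_series(res.series, tau)
    corr = gp.match_lesions(sets)
    bitv = gp.build_bitv(corr, sets, corr.lesion_ids[0])
    print(f"     {amp:4.0f}        {gp.volume_cc(bitv):6.2f}")

print()
print("The conventional (non-gated) workflow has to cover this excursion with")
print("a blanket 5 mm radial / 10 mm craniocaudal margin; the gated workflow")
print("measures it per lesion and only adds a 3 mm set-up margin on top.")
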