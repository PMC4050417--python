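"""Partial-volume bias of threshold segmentation, pinned by an analytic oracle.

A 16 cc sphere (SUV 7.9) in a warm liver background (SUV 2.97) is blurred by
a 6 mm FWHM Gaussian point-spread function. Segmenting at a threshold just
above the background catches the blurred halo, so the measured volume
overestimates the true 16 cc — the mechanism behind threshold-at-background
volume inflation on physical phantoms. The voxel pipeline is compared with
the closed-form iso-surface volume of the blurred sphere.
"""

import gatedpet as gp
from gatedpet.phantom import FWHM_TO_SIGMA

phantom = gp.simulate_gated(gp.torso_preset("torso16"))  # noiseless, static
tau = 3.2  # a typical measured background SUVmax, just above the true 2.97

mask = gp.threshold_segment(phantom.series[0], tau)
lesions = gp.label_lesions(mask, min_volume_cc=0.1)
measured = max(l.volume_cc for l in lesions)

sigma = 6.0 * FWHM_TO_SIGMA
oracle = gp.analytic_blurred_sphere_volume(gp.sphere_radius_mm(16.0), 7.9, 2.97, sigma, tau)

print(f"true sphere volume      : 16.00 cc")
print(f"segmented volume        : {measured:.2f} cc  (+{100 * (measured / 16 - 1):.0f}%)")
print(f"analytic oracle volume  : {oracle:.2f} cc")
print(f"pipeline vs oracle      : {100 * (measured / oracle - 1):+.1f}%")
print()
print("The overestimate is positive by construction: the iso-SUV surface at a")
print("near-background threshold lies outside the true sphere once the PSF")
print("smears activity outwards. Raising tau shrinks the mask monotonically.")
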