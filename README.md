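# gatedpet

Respiratory-gated (4D) PET target-volume delineation for liver SBRT
planning: individualized SUV-threshold tumour segmentation, internal target
volume construction across respiratory phases, planning-margin expansion,
and the cohort statistics to compare the gated and conventional workflows —
together with a synthetic gated-PET phantom generator so that every stage is
testable without scanner data.

## The problem

Liver metastases move 1–2 cm with breathing. A conventional FDG-PET exam
averages over the breathing cycle, so a moving lesion is smeared: its
apparent uptake drops (small lesions can vanish entirely) and its true
excursion is unknown, forcing blanket planning margins. A respiratory-gated
(4D) PET bins the acquisition into phases of the breathing cycle and freezes
the motion in each bin.

## The method

Volumes follow the ICRU margin chain, with PET supplying the biology:

* **Threshold** — healthy-liver background SUVmax, measured in 20–30 cc
  spherical ROIs: 3 ROIs when they agree within 0.1 SUV, 5 when within
  0.1–0.2; their mean is the patient-specific threshold τ. A voxel is
  tumour iff SUV > τ (strict).
* **BTV** — connected supra-threshold component on one image (a gated phase
  or the non-gated exam).
* **BITV** = ⋃ over the six phases of each lesion's per-phase BTV: the
  internal target volume measured, not assumed.
* **PTVg** = BITV ⊕ 3 mm isotropic (set-up margin only).
* **PTV** = CTV ⊕ 5 mm radial / 10 mm craniocaudal (set-up + assumed
  motion), the conventional plan it is compared against.
* **Statistics** — paired per-lesion comparison with the exact Wilcoxon
  signed-rank test (zeros dropped, mid-ranks for ties, full sign
  enumeration by dynamic programming).

The phantom module simulates hot spheres in a warm liver-like background
with craniocaudal sinusoidal motion, Gaussian PSF blur and optional noise,
binned into six phases plus the time-averaged non-gated image, and ships a
closed-form oracle for the iso-SUV volume of a blurred sphere.

## Worked example

```python
import gatedpet as gp

phantom = gp.simulate_gated(gp.torso_preset("torso16"))   # 16 cc sphere, SUV 7.9
tau = 3.2                                                 # measured background SUVmax
lesions = gp.label_lesions(gp.threshold_segment(phantom.series[0], tau))
measured = max(l.volume_cc for l in lesions)
oracle = gp.analytic_blurred_sphere_volume(
    gp.sphere_radius_mm(16.0), 7.9, 2.97, 6.0 / 2.3548, tau)
print(f"{measured:.2f} cc vs oracle {oracle:.2f} cc")
```

prints `31.58 cc vs oracle 31.23 cc`: thresholding a 6 mm-FWHM-blurred
16 cc sphere just above its background inflates the volume (here +97%, the
partial-volume mechanism seen on physical phantoms), and the voxel pipeline
agrees with the analytic iso-surface volume to ~1%.

The `examples/` directory walks each capability: the threshold protocol,
partial-volume bias, BITV growth with motion amplitude, a moving lesion
visible only on the gated exam, the cohort statistics (exact Wilcoxon
p = 0.00525 for PTV vs PTVg and 0.00305 for BITV vs BTV on the packaged
14-lesion table), and the two planning workflows end to end. A thin CLI
(`gatedpet simulate | delineate | expand | cohort-stats | report`) wraps the
same functions for shell use.

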