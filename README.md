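# mrsimqa

Phantom-based quantitative characterization and routine QA analyses for a
radiotherapy-dedicated MR simulator (MR-SIM), with a synthetic-phantom
generator standing in for the scanner.

When an MRI scanner is used as the *sole* simulation modality for radiation
therapy planning, its geometric and quantitative fidelity must be
characterized and then monitored: geometric distortion grows with distance
from the magnet isocenter, the main field B0 drifts, slice profiles
deviate from nominal, respiratory-resolved (4D) acquisitions trade scan
time for motion sampling, and bone — nearly invisible at conventional echo
times — must be recovered with ultrashort-TE (UTE) imaging.  `mrsimqa`
implements the full analysis chain for each of these measurements and a
generator that renders every phantom involved with known ground truth, so
the whole pipeline is testable end to end without a scanner.

## What it computes

| Module | Measurement |
| --- | --- |
| `mrsimqa.distortion` | Marker detection (center of mass), one-to-one matching, displacement vector field **d** = measured − reference; per-shell stats of \|d\| over a 5 cm sphere and 5–20 cm annuli; 2D isocontours (2–6 mm) and the daily-QA rectangle in which ≥75 % of control points have \|d\| < 2 mm |
| `mrsimqa.b0` | Dual-echo phase difference Δφ = wrap(φ(TE₂) − φ(TE₁)), spatial unwrapping, ppm = (Δφ − ⟨Δφ⟩)/(2π f₀ ΔTE)·10⁶, and the volume RMS over a spherical volume (DSV), vs the ACR < 2 ppm recommendation |
| `mrsimqa.spatial` | Line-profile marker peaks (sub-voxel refinement), spacing vs nominal; half-maximum threshold segmentation and volume comparison with equivalent diameter (6V/π)^(1/3) |
| `mrsimqa.fourd` | Amplitude-triggered 4D-MRI simulation: trigger-level calibration over the first two breathing cycles, slice-by-slice acquisition timeline, duty cycle = nominal programmed time / overall scan time, phase-sorted volumes, MIP and S-I motion-envelope extent |
| `mrsimqa.utedixon` | Flexible-TE two-point Dixon water/fat separation (s(TEₖ) = ρ_w + ρ_f e^{i2πΔf TEₖ}), bone-enhanced image = 1.3·UTE − in-phase, body-surface halo cleanup, ROI contrast |
| `mrsimqa.qa` | Central-frequency drift (< 1.5 ppm/day), crossed-ramp FWHM slice thickness, laser offset/motion tolerances, JSON/CSV QA reports |
| `mrsimqa.synthetic` | Every phantom above: capsule grid (2.5/2.7 cm spacing, ~2450 markers) with a parametric distortion model, 31 cm B0 sphere with programmed ppm maps, crossed-ramp insert, water/fat/bone/air multi-echo object, respiratory waveforms and a translating motion phantom |

## Worked example

Measure 3D distortion of a synthetic grid-phantom pair distorted by a
radial cubic model reaching 2 mm at 150 mm from isocenter:

```python
import numpy as np
from mrsimqa import synthetic as syn, distortion as dst

model = syn.DistortionModel.cubic(2.0, 150.0)   # |d| = 2 mm at r = 150 mm
ref, meas, truth = syn.gen_grid_phantom_pair(model=model)
field, summary = dst.analyze_pair(ref, meas)
print(summary.table[["r_min_mm", "r_max_mm", "n", "mean_mm", "max_mm"]])
```

```
   r_min_mm  r_max_mm     n   mean_mm    max_mm
0       0.0      50.0    32  0.039709  0.057512
1      50.0     100.0   232  0.360741  0.606262
2     100.0     150.0   568  1.310415  2.021547
3     150.0     200.0  1160  3.370020  4.756618
```

Each row is a radial shell about the isocenter: within 5 cm the mean
distortion is ~0.04 mm (the model is nearly zero there), while in the
15–20 cm shell the mean reaches 3.4 mm and the maximum 4.8 mm — the
characteristic growth of gradient-nonlinearity distortion toward the edge
of the field of view.  The analytic shell means of the generating model
agree with these measured values to better than 0.01 mm.

The command line mirrors the library:

```
mrsimqa simulate --what grid --out /tmp/grid
mrsimqa distort3d --ref /tmp/grid_ref.nii.gz --meas /tmp/grid_meas.nii.gz --out summary.json
mrsimqa b0map --phase1 p1.nii --phase2 p2.nii --te1 10 --te2 12 --dsv 310 --out b0.json
mrsimqa fourd --period 3 --phases 10 --slices 25 --tr 2000 --out study.json
mrsimqa qa-daily --frequency 42587276 --previous 42587318 --out qa.json
```

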