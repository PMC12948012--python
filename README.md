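# speckleflow

Scanning modulated-pattern X-ray multi-contrast imaging: a physics
simulator with exact ground truth, the classical speckle-vector-tracking
baseline (XSVT), Frankot–Chellappa phase integration, and a
multi-resolution cost-volume neural network that retrieves absorption,
refraction/phase and dark-field simultaneously from a pair of scan
stacks.

## The problem

Speckle-based imaging (SBI) and grating interferometry modulate the X-ray
beam with a structured pattern — a lithographed coded mask, a Talbot
checkerboard grating, or sandpaper — and scan it across N positions while
recording the pattern with and without the sample. The sample distorts
the pattern through three channels:

* **transmission** `T(x, y)` — absorption scales the local intensity;
* **refraction** — the transverse phase gradient deflects the beam by
  α = (λ/2π)∇φ, displacing the pattern by δ = d·α/p detector pixels;
* **dark-field** `D(x, y)` — unresolved small-angle scattering damps the
  local pattern contrast toward its smooth envelope.

Per frame `i`:

    I_s(x, y, i) = T · [ (1 − D) · I_r(x + δx, y + δy, i)
                         + D · Ī_r(x + δx, y + δy, i) ]

Classical retrieval tracks each pixel's intensity vector across the scan
dimension by cross-correlation (XSVT) and integrates the recovered
gradients into a phase map (Frankot–Chellappa). That works well for
N on the order of tens, but acquisition and analysis time grow with N.
The network in this package — a coarse-to-fine feature pyramid with
physical warping, a local-correlation cost volume, per-level flow
estimators and transmission/dark-field heads — retrieves all contrast
channels in one pass and degrades gracefully down to a few scan
positions. It is aimed at methods developers in X-ray phase-contrast
imaging who need a controlled, fully synthetic testbed with known ground
truth.

## Worked example

Simulate a beryllium parabolic lens (apex radius 200 µm) behind a 5 µm
coded mask at 14 keV, 0.5 m propagation, 0.65 µm pixels; track it with
XSVT and integrate the phase:

```python
import numpy as np
from speckleflow import (
    OpticsConfig, apply_sample, displacement_to_refraction,
    generate_coded_mask, make_lens_phantom, make_trajectory,
    refraction_to_phase, render_reference_stack, xsvt_track,
)
from speckleflow.xsvt import TrackingConfig, fill_invalid

optics = OpticsConfig(energy_keV=14.0, distance_m=0.5, pixel_size_um=0.65)
lens = make_lens_phantom(200.0, 1.8e-6, optics.wavelength_m, (256, 256), 0.65)
mask = generate_coded_mask(shape=(352, 352), seed=3)
scan = make_trajectory("xy-grid", 25, 3.0, jitter=0.3, seed=3)
reference = render_reference_stack(mask, scan, optics, (256, 256))
sample = apply_sample(reference, lens, optics)

disp, corr = xsvt_track(reference.frames[:20], sample.frames[:20],
                        TrackingConfig(search_window=3, min_valid_correlation=0.2))
ax, ay = displacement_to_refraction(fill_invalid(disp), optics)
phase = refraction_to_phase(ax, ay, optics)

truth = lens.phase - lens.phase.mean()
rel = np.sqrt(((phase - truth) ** 2).mean()) / np.abs(truth).max()
print(f"peak phase {np.abs(truth).max():.1f} rad, relative RMS error {100 * rel:.2f}%")
```

Output:

```
peak phase 2.3 rad, relative RMS error 0.47%
```

The lens imposes a peak phase of ~2.3 rad over the 256-px frame
(displacements up to ~0.9 px); tracking twenty scan positions recovers
the displacement field to a few hundredths of a pixel, and the integrated
phase agrees with the analytic parabola to half a percent of its peak.

The same pipeline is available from the shell:

```
speckleflow --out-dir run --seed 3 simulate --preset lens --size 128
speckleflow --out-dir run track run/reference.tiff run/sample.tiff --min-correlation 0.2
speckleflow --out-dir run integrate run/tracking.tiff
```

and `speckleflow train` / `infer` / `evaluate` drive the desk-scale
network (see `docs/methods.md` for the model and training schedule).

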