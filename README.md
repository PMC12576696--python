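# qbrm

Quantitative birefringence microscopy (qBRM) analysis of myelin debris:
simulation and inversion of polarized-light parameter maps, sliced
small-object detection of debris in large tiled images, ROI-normalized
density profiling along the rostro-caudal axis, and group-level statistics.

## The problem

Myelin — the lipid sheath around axons — is birefringent, so polarized
light reads out its density and organization without any stain.  After a
cortical injury, axons disconnected from their cell bodies degenerate
(Wallerian degeneration) and their myelin fragments into vesiculated
debris, 1–10 µm spheres scattered through white-matter tracts such as the
corpus callosum.  Counting that debris across whole serial sections tells
you where the damage projects and how fast it clears — but the objects are
tiny, the images are huge, and the counting must be automated.

This package implements that workflow end to end for people who analyze
(or simulate) qBRM data:

1. **Image formation and inversion.**  With illumination linearly
   polarized at angle θ and a circular analyzer, a thin birefringent
   sample transmits

   &nbsp;&nbsp;&nbsp;&nbsp;I(θ) = (I₀/2)·[1 + sin δ · sin 2(θ − φ)]

   where δ is the phase retardance and φ the in-plane optic-axis
   orientation (180°-periodic).  Frames at N ≥ 3 angles determine, per
   pixel, the relative retardance |sin δ| (a proxy for myelin density) and
   φ, via a least-squares fit of the second-harmonic model
   I = c₀ + c₁cos 2θ + c₂sin 2θ.  Maps are rendered as RGB with hue = 2φ
   and brightness = |sin δ|; the crossed-circular-polarizer mode
   I = I₀·sin²(δ/2) is also modeled.

2. **Debris detection.**  Intact fibers carry an optic axis perpendicular
   to their direction (the lipids wrap the axon); a debris vesicle carries
   a *radially varying* optic axis.  Detection runs per 128 px tile with
   50 % overlap (sliced inference), with optional test-time augmentation
   including "color rotation" — a cyclic RGB permutation equal to a 60°
   shift of the orientation color wheel — and greedy non-max suppression.
   The detector is pluggable; the bundled reference implementation is a
   rotational matched filter on the doubled-angle orientation field,
   calibrated on annotated patches.

3. **Quantification.**  Detections inside a manually drawn ROI are
   reduced to one density per section (count/mm²); per-animal profiles
   along the rostro-caudal axis are re-zeroed at the maximum-damage plane;
   per-animal maxima feed a one-way ANOVA with Tukey's HSD across
   recovery groups.

4. **Synthetic data.**  A generator produces sections (coherent fiber
   tracts + annular debris with radial optic axes + acquisition noise),
   polarization stacks, and whole cohorts with a unimodal damage profile
   and lognormal between-animal variability — so every stage is testable
   with exact ground truth.

## Worked example

```python
import numpy as np
from qbrm.core import reconstruct_parameter_map, render_rgb
from qbrm.detect import (TilingConfig, crop_training_patches,
                         sliced_inference, train_reference_detector)
from qbrm.quantify import compute_density
from qbrm.stats import detection_metrics, match_detections
from qbrm.synth import (SectionSimConfig, generate_polarization_stack,
                        generate_section_truth)

# simulate a 0.26 mm^2 corpus-callosum-like section with known debris
config = SectionSimConfig(image_height_px=512, image_width_px=512,
                          debris_density_per_mm2=40.0, seed=7)
truth = generate_section_truth(config)
stack = generate_polarization_stack(truth, config)

# invert the 4-angle stack and render the orientation-colormapped RGB
pmap = reconstruct_parameter_map(stack)
rgb = render_rgb(pmap)

# calibrate the reference detector on three annotated training sections
patches = []
for seed in range(3):
    t_cfg = SectionSimConfig(image_height_px=512, image_width_px=512,
                             debris_density_per_mm2=60.0, seed=seed)
    t_truth = generate_section_truth(t_cfg)
    t_rgb = render_rgb(reconstruct_parameter_map(
        generate_polarization_stack(t_truth, t_cfg)))
    patches += [(p, b) for p, b, _ in crop_training_patches(
        t_rgb, t_truth.debris_boxes, TilingConfig())]
detector, log = train_reference_detector(patches)

# sliced whole-image inference (128 px tiles, 50% overlap) + density
result = sliced_inference(rgb, detector, TilingConfig())
density = compute_density(result.detections, truth.roi)
report = detection_metrics(
    match_detections(result.detections, truth.debris_boxes, 0.3))
```

Output:

```
simulated debris objects: 15
mean retardance in tract: 0.151
calibrated threshold: 0.34 (training F1 0.741)
detections: 14  sensitivity 0.67  PPV 0.71
defect density: 53.4 /mm^2 (true 57.2 /mm^2)
```

The section truly contains 15 debris objects (57.2/mm²); the detector
(calibrated here on a deliberately small training set of three sections)
recovers 14 boxes of which 10 are correct.  Misses concentrate in
sub-resolution (1–2 px) debris and occur at a roughly density-independent
rate, which is why density comparisons across sections remain linear even
with imperfect sensitivity (see `docs/methods.md`).

A command-line interface mirrors the library:
`qbrm run --config cfg.yaml` executes
simulate → reconstruct → detect → quantify → stats and writes CSV/JSON
outputs plus a run manifest; `qbrm reconstruct`, `qbrm detect`,
`qbrm quantify`, `qbrm profile`, `qbrm evaluate` and `qbrm stats` run the
individual stages on files.

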