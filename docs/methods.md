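# Methods

## Image-formation model

The forward model for the rotating-polarizer / circular-analyzer
acquisition is the standard Jones-calculus result for a thin linear
retarder between a rotating linear polarizer and a circular analyzer:

    I(θ) = (I₀/2) · [1 + sin δ · sin 2(θ − φ)]

with θ the illumination polarization angle, δ the phase retardance and φ
the in-plane optic-axis orientation.  Only the second harmonic in θ
appears; the sign convention is pinned by the forward→inverse round-trip
requirement rather than by any external reference.  The relative
retardance is reported as |sin δ| ∈ [0, 1], never δ itself — this matches
the quantity the instrument actually constrains and avoids the arcsin
branch ambiguity.  The crossed-circular-polarizer observable is
I = I₀ sin²(δ/2), orientation-free by construction.

Orientation convention throughout: degrees counterclockwise from the +x
image axis, modulo 180°, 0-based pixel grid, origin top-left, y down.

## Inversion

Per pixel, the model I = c₀ + c₁cos 2θ + c₂sin 2θ is fit by unweighted
least squares over the N ≥ 3 angles (normal equations of the 3-column
harmonic design, one 3×3 solve shared by all pixels).  Then

* |sin δ| = √(c₁² + c₂²) / c₀, clipped to [0, 1];
* φ = ½·atan2(−c₁, c₂) mapped into [0, 180°).

Pixels with c₀ ≤ 0 or retardance below a validity floor (default 0.01)
get an undefined orientation: the phase of a near-zero modulation is
noise.  The design matrix is rank-checked; angle sets that collapse
modulo 180° are rejected.  On noise-free synthetic stacks the round trip
is exact to ~1e-13 relative; the tests enforce ≤1e-9 on a 50×50 parameter
grid at N ∈ {3, 4, 6}.

## Colormap

RGB rendering uses hue = 2φ on a full-saturation piecewise-linear hue
wheel, value = |sin δ|, invalid pixels black.  Because the wheel completes
one cycle per 180° of orientation, a cyclic channel permutation
(R,G,B) → (B,R,G) equals a +60° orientation shift.  The three channels are
computed from hue offsets of exactly 0/120/240°, so this identity holds
*bit-exactly* whenever the orientation values are exactly representable;
the test sweeps a 0.25°-step (dyadic) grid where all intermediate float
arithmetic is exact.

## Synthetic sections

The generator emulates a coronal corpus-callosum section at ~1 µm/pixel
(10× regime):

* **Fibers** — straight anti-aliased streaks with Gaussian cross-profile
  (σ ∈ [0.8, 1.6] px, amplitude ∈ [0.45, 0.70]), orientation drawn from
  the tract axis ± jitter (default 6° s.d.), added until a target area
  fraction (default 0.3) is covered.  A streak carries optic axis =
  streak direction + 90°, because myelin's lipid layers wrap the axon.
* **Debris** — count ~ Poisson(density × area); diameters uniform on
  1–10 µm; each object is an annulus with a bright rim (amplitude
  0.80–0.95) of width 20 % of the radius, a dim core (30 % of rim), a
  ~1 px anti-aliased outer edge, and a *radial* optic axis over the whole
  disk.  The tight bounding box of the rendered footprint is the ground
  truth.  Sub-resolution objects (d ≲ 2 px) render as one or two dim
  pixels — deliberately: partial-volume dimming is what a camera would
  see.
* **Background** — retardance 0.03 with uniformly random orientation.
* **Acquisition** — one frame per illumination angle via the forward
  model, additive Gaussian noise with s.d. = noise_sd_frac (default 0.02)
  × mean intensity, clipped at zero.

What the generator does **not** model: point-spread blur and defocus, 3-D
inclination of fibers, crossing-fiber geometry beyond chance overlap,
stitching artifacts, tissue wrinkles, staining/IHC ground truth.  Passing
tests therefore show the pipeline's logic and statistics are correct for
this object model; they do not certify performance on real tissue, where
transverse axons and artifacts add false-positive modes the simulator
does not produce.

## Cohorts

A cohort draws, per animal, a peak density = group mean × lognormal
multiplier (unit mean, configurable CV; the study system shows marked
between-animal variability) and a damage-peak position = nominal peak +
Gaussian anatomical jitter (default 300 µm s.d., which is what makes
normalizing profiles to the maximum-damage plane a meaningful step).
Per-section expected density follows a Gaussian bump (default FWHM
1800 µm) over a baseline, sampled at the configured spacing (default
600 µm, 10 sections/animal, positions centered on the nominal peak).
Each section's realized count is Poisson with mean density × analyzed
area (default 5 mm², the scale of a sampled corpus-callosum ROI).  Seeds
derive from SeedSequence([cohort_seed, animal, section]) so any section
is independently reproducible.  Default group structure: 6-week recovery
(n = 4, 40 /mm²), 12-week (n = 4, 8 /mm²), controls (n = 3, 5 /mm²),
CV 0.3, baseline 1 /mm².

## Reference detector

The exact detector used in large-scale studies of this kind (a
COCO-pretrained YOLOv4-Tiny) is deliberately out of scope; the detection
stage defines a pluggable `DetectorInterface` and ships a fully
deterministic matched-filter reference implementation:

1. The RGB patch is inverted to a brightness map v and the doubled-angle
   field u = (v − v_floor)₊ · exp(2i·hue); v_floor (default 0.15)
   suppresses background.
2. For each candidate radius r, u is correlated against Gaussian ring
   templates exp(2iψ) split into angular sectors (quadrants; octants once
   r ≥ 3 affords ~2 px of arc per sector).  At a debris center every
   pixel phase matches the template phase; a fiber ridge responds with
   phase π (its axis is perpendicular to its brightness ridge), and a
   ring tangent to a fiber lights only two opposite sectors.  The score
   is the minimum sector response, real part, normalized by the
   analytically rendered ideal-annulus response — a normalized
   correlation in [0, 1] that only a full radial annulus can drive high.
   The score is further multiplied by a ring orientation-diversity
   factor, 1 − |⟨u⟩|/⟨|u|⟩ over the ring (rescaled so diversity ≥ 0.5
   passes unpenalized): a radial annulus contains every optic-axis
   direction so its doubled-angle ring mean vanishes, whereas fiber
   clutter is orientation-coherent however its brightness is arranged —
   including gratings of near-parallel fibers whose Bessel-J₂ ring
   response would otherwise light every sector positively.
3. A separate "dot" channel catches sub-resolution debris: minimum over
   four quadrants of (center brightness − quadrant ring brightness),
   normalized by the rim amplitude.  An isolated dot beats all four
   quadrants; any pixel on or at the end of a fiber fails at least one.
4. Peaks above threshold (3×3 local maxima, capped at 64/scale) emit
   boxes refined to the bright footprint near the peak; cross-scale
   duplicates are merged by IoU plus center-containment (plain IoU cannot
   suppress a 3 px box inside an 11 px box).

Training is closed-form calibration on annotated patches: scales from the
2nd–98th percentile of annotated box radii (half-integer steps below
r = 3), rim amplitude from the box brightness median, and per-channel
thresholds from a sweep (0.10–0.98, step 0.04) choosing the training-F1
maximum, ties toward the more precise threshold; the dot channel is kept
only if it raises recall without costing more than 5 points of precision.
Emitted confidences are rescaled so each channel's decision boundary maps
to 0.5.  The `TrainConfig` schedule fields (100 epochs, Adam-style lr
0.005 halved every 10, batch 256) are part of the detector contract and
are recorded in the training log; the matched filter has no iterative
phase to consume them, but a neural backend plugged into the same
interface would.

On held-out synthetic sections the calibrated detector typically reaches
sensitivity ≈ 0.7–0.8 and PPV ≈ 0.85–0.95 at IoU 0.3 (the residual misses
are dominated by sub-resolution debris).  Because the miss rate is
roughly density-independent, per-section density remains linear in the
true density — the same argument the field uses when a detector with
imperfect sensitivity still quantifies relative pathology.

## Sliced inference

Tiles are 128 px with 50 % overlap, grid anchored at (0, 0), last
row/column shifted inward so all tiles are full size.  Per tile (and per
TTA variant: dihedral transforms × the three color rotations) the
detector runs on the transformed patch; boxes are mapped back through the
inverse transform and tile origin, accumulated, confidence-filtered
(default 0.25) and merged by one global greedy NMS (default IoU 0.5).
Detections whose center falls inside a tile's overlap margin are dropped
unless that edge is the image border: with ≥ 50 % overlap every object is
seen well inside some tile, and the margin copies are the ones distorted
by kernel truncation.  A detector failure on a tile skips that tile and
is reported in the result summary.

The matched-filter score uses the correlation's real part, so it is *not*
intrinsically invariant to color rotation (a global hue shift rotates the
correlation phase); invariance is restored exactly by TTA over the three
color rotations — which is precisely the augmentation's stated purpose.

## Quantification and statistics

* ROI membership is **center-in** (boundary inclusive): unambiguous and
  count-stable for small objects.  Areas come from the polygon (shoelace,
  via shapely) or mask pixel count, times (µm/px / 1000)².
* Each section is one number: in-ROI count / ROI area (the within-section
  debris distribution is treated as homogeneous).
* Damage profiles sort sections by rostro-caudal position (µm, positive =
  anterior) and re-zero at the argmax-density section; ties break toward
  the most posterior section and are flagged; an all-zero profile has an
  undefined peak and skips normalization.
* Validation sampling picks floor(fraction × ROI area / tile area)
  tile-aligned squares fully inside the ROI at even index spacing, with a
  seeded cyclic start offset.
* Detector scoring: greedy one-to-one matching by descending confidence
  at IoU ≥ 0.3 (0.5 is overly strict for objects a few pixels across).
  Sensitivity = tp/(tp+fn), PPV = tp/(tp+fp); the "false-positive rate"
  is reported both as fp/(tp+fp) (algebraically 1 − PPV) and as FP/mm²,
  because published figures of this kind sometimes use an unstated third
  denominator and the two conventions are not interchangeable.
* Group test: one max-density value per animal; one-way fixed-effects
  ANOVA by explicit sums of squares; Tukey HSD with Tukey–Kramer standard
  errors sqrt(MSW/2·(1/nᵢ+1/nⱼ)) and p-values from the studentized-range
  distribution; significance at α = 0.01 for the headline comparison.
  Independent cross-checks in the tests: `scipy.stats.f_oneway` and
  `scipy.stats.tukey_hsd` (agreement to 1e-6).

## Problem sizes and numerical choices

Test and acceptance runs use sizes chosen to make the statistics, not the
wall clock, the binding constraint: detector training on ~490 patches
from ten 512² sections at 60 /mm²; density linearity on fifteen 896²
held-out sections spanning 5–95 /mm² (large enough that binomial counting
noise is small against the density spread); oracle tiled-inference on
640² sections; profile recovery on 100 single-animal cohorts at the
12-week-like density (8 /mm², the weakest group with measurable damage);
the significance pattern on 200 cohorts at the default group structure.
The oracle tiled-inference check runs NMS at IoU 0.6 rather than the 0.5
default: cross-tile duplicates of the same object have IoU 1 and are
still merged, while two legitimately overlapping Poisson-placed objects
(which NMS at 0.5 would wrongly collapse) survive.

Degenerate inputs are rejected early: < 3 angles or angles equal modulo
180°, images smaller than one tile or one maximum-diameter debris object,
zero-area ROIs, self-intersecting polygons, empty training sets, groups
with n < 2 for ANOVA, zero reference variance for the density regression.

## Known limitations

* The annulus/streak object model is stylized; real debris is irregular
  and real tracts contain crossing and inclined fibers that produce
  false-positive modes absent here.
* The matched filter is specific to radially symmetric objects; it will
  not generalize to other defect morphologies without a new template (or
  a learned detector behind the same interface).
* Detector sensitivity degrades for objects at the resolution limit
  (1–2 px); density estimates inherit a sub-unity slope that is stable
  but not corrected for.
* No Mueller-matrix effects, diattenuation, or 3-D inclination; the maps
  are strictly 2-D.
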