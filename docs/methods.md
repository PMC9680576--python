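# Methods

This note documents the models, conventions and numerical choices behind
`bevroi`, and what the synthetic experiments do and do not demonstrate.

## Digital skull phantom

The phantom stands in for a printed-and-filled physical skull: an
ellipsoidal shell (default outer semi-axes 72 × 92 × 78 mm, ~2160 cm³
nominal volume) of 400 HU bone surrogate around a 36.1 HU soft-tissue
fill, air outside (−1000 HU), and a metal BB at isocenter. Structural
elements are chosen to reproduce the *statistics* a registration
algorithm meets in real cranial MV images, not any particular anatomy:

- **Asymmetric surface undulations** (seeded low-order cosine series on
  the direction angles, ≲2% radial amplitude) so that no beam's-eye view
  is rotationally degenerate.
- **Direction-modulated shell thickness** with an additional
  higher-frequency ripple term (suture/ridge scale). Projected shell
  path length then varies across the whole BEV, texturing the mid-skull
  region that would otherwise be a featureless ramp.
- **Sinus-like air cavities** in the anterior interior and two
  **mastoid-like clusters of small air cells** (1.5–4 mm radius,
  posterior-lateral, mirrored). Air against soft tissue is the
  strongest contrast available at MV energies; the cell clusters are
  what makes lateral views registrable, exactly as mastoid air cells
  dominate real lateral skull radiographs.
- **Bony landmark nodules** (default 24, radius 3–8 mm) scattered at
  60–90% of the inner radius, clear of the BB-removal neighborhood, so
  every BEV contains compact 2-D features.
- **BB**: 2 mm diameter at isocenter, default 20 000 HU. Under the
  linear HU→μ ramp used for DRRs this is ~21× water attenuation,
  approximating a steel fiducial at MV energies; a lower value would
  leave the BB comparable to bone structure and break the premise that
  the fiducial dominates any disk-matched convolution response.

Default voxel spacing is 0.625 mm isotropic (CT-resolution scale);
reduced-resolution runs use 1.0 mm (see "Problem sizes"). Optional
Gaussian HU noise (off by default) models CT acquisition noise; DRR line
integrals average it out almost entirely. Generation is bit-reproducible
per seed.

Before reference-DRR generation, a voxel-aligned 60 × 60 × 40
neighborhood around the BB is overwritten with the fill HU so the
fiducial cannot inform anatomy registration; simulated EPID images keep
the BB.

**What the phantom does not emulate**: true cranial anatomy (orbits,
mandible, teeth, foramina), bone-density heterogeneity, scatter and
detector physics, and CT artifacts. Passing tests therefore show that
the search/registration/correction machinery behaves correctly on
skull-like image statistics; absolute error magnitudes on real patients
depend on real contrast and are expected to differ.

## Geometry and coordinate conventions

Fixed room frame: x lateral, y longitudinal, z vertical, isocenter at
the origin. The gantry rotates about y with the source above the supine
patient at gantry 0; the couch rotates the patient about z. Plan
(Eclipse-scale) couch angles convert to the internal rotation via
`couch_IEC = (360 − couch) mod 360`.

The gantry sense and BEV axes are fixed by requiring the couch-shift
matrix (see README) to be an *exact projection*: source(θ) =
SAD·(−sin θ, 0, cos θ), BEV x axis u = (cos θ, 0, sin θ), BEV y axis
v = ŷ. With these definitions the identity

derive_couch_shift(P_bev(t), θ, φ) = couch-frame component of t
perpendicular to the beam

holds to machine precision (property-tested over random inputs), and the
transform preserves the displacement norm. Whether this sense matches a
particular vendor's physical rotation direction is unobservable on a
synthetic phantom; converters are documented and centralized.

Arc enumeration: a near-full arc (span within one control-point spacing
of 360°) is treated as closed and does not duplicate its coincident
endpoint (the 180.1→179.9 CW axial arc yields 72 points at 5°); partial
arcs include both endpoints (the two couch ±45° arcs yield 38 each).

## DRR model

Radiological paths are computed by Siddon/Amanatides–Woo parametric
voxel traversal (exact per-voxel chord lengths; numba kernel), validated
against a 0.05-voxel-step ray-marching oracle to <0.5% relative error.
Pixel intensity is `exp(−∫μ dl)` with `μ = μ_water (1 + HU/1000)`
clamped at zero and `μ_water = 0.00505 /mm`, an effective
single-energy value for the 2.5 MV imaging-beam regime; the transform
is configurable because any monotone intensity mapping leaves MI
registration unchanged. EPID magnification: pixel pitch at the
isocenter plane is `panel_pitch × SAD/SID`, with SID 1500 mm for the
axial arc (EPID at 50 cm) and 1800 mm for the couch-rotated arcs
(80 cm). Detector default 1190² pixels at 0.336 mm.

## Registration

Translation-only, deterministic, in three stages:

1. **Coarse**: integer-pixel MI grid search (50-bin joint histogram of
   quantized intensities, numba) over ±bound (default 3 mm), stride 2
   then unit refinement.
2. **Refinement**: hierarchical 3×3 hill-climb with cubic-spline
   sub-pixel sampling of the reference and partial-volume (linear) soft
   binning on the sampled axis, so MI is continuous in the shift; step
   halves from 0.25 px down to the 0.005 mm resolution target, clamped
   to the search bound.
3. **Polish** (used by the general two-image API): two dense 5×5 local
   sweeps (0.08 and 0.02 px) step over micro-ripple local maxima of the
   sampled-MI landscape.

Images are preprocessed by min-max normalization, 256-level histogram
equalization and a final rescale to [0, 1]. A small crop registers
against the *full* reference image (template style), which handles
apertures down to the 0.375 cm² minimum. Pixel sets are decimated to a
sample budget (2 500 for ranking, 8 000 for plan evaluation, 60 000 for
the precision API); registration error scales with detector pitch, so
precision-sensitive checks run at clinical pitch. The stochastic
one-plus-one optimizer of the clinical platform is replaced by this
deterministic search for reproducibility; the platform's initial-radius
setting is retained as provenance metadata only.

The aperture-ranking stage applies its scoring shifts *off the detector
pixel lattice* (±1.8 mm at 0.4167/0.5 mm pitches). Integer-pixel
applied shifts produce exact-copy crops that any aperture registers
perfectly, masking direction-degenerate apertures (those lying on a
single smooth edge); off-lattice shifts expose them. The error-scoring
grid is configurable (default 10×10 over ±2 mm, which contains no zero
shift); the MI shift surface uses the 11×11/±2 mm grid (121 values).

BB detection: negative-log (attenuation) image, smooth-background
subtraction (Gaussian, σ = 2×BB diameter), disk matched filter,
suppression of thresholded connected components larger than 1.5× the
BB's physical size, then an intensity-weighted centroid with weights
soft-floored at 50% of the local peak. The floor and the 4×MAD outlier
threshold were set for sub-0.02 mm static accuracy of a centered
fiducial and robustness to background texture.

## Aperture search

Sampling: area log-uniform over 0.375–37.5 cm², aspect ratio uniform on
[1/3, 3] (restricted per-draw so the rectangle fits), center uniform
over containment in the 22 × 22 cm² open field. Scoring: per grid
shift, error = detected − applied; ranking scalar = mean(|error|) +
SD(error) (the simplest additive combination of the two stated
objectives); registration failure ⇒ score +∞. Selection: the lowest
⌊n/10⌋ scores, ties broken by smaller area then sampling order.
Threshold aperture: bounding rectangle of the largest connected
component of the superlevel set at level% of the topographic-map
maximum; superlevel nesting makes the extracted area non-increasing in
level. Good/bad labels (range <0.1 mm & |mean| <0.1 mm vs range >1 mm,
areas ≥4 cm²) use the refined registration; the 3000-aperture search
ranks with the fast integer+parabolic registration, which preserves
ordering at a fraction of the cost. Optional snapping of extracted
rectangles to 2.5 mm leaf widths is off by default (apertures are
treated as ideal rectangles).

## Motion simulation

Traces are per-control-point couch-axis offsets: linear drift
(magnitude × i/(N−1) per axis) or a sudden step at an onset index
(default: halfway through the first, axial arc). Delivery simulation is
open-loop: the phantom is rigidly displaced, an EPID image is computed
(full DRR of the displaced volume, cropped to the aperture; optional
seeded Poisson noise), and the couch correction is derived per point
with no feedback — matching a decoupled acquire-then-analyze workflow.
BB tracking uses a 2.5 × 2.5 cm² jaw field and is the gold standard;
anatomy registration uses the plan aperture against the BB-free
reference DRR. Because the BEV→couch transform is linear, the 3D norm
of the correction discrepancy equals the 2D BEV discrepancy; both are
reported, with flagged (failed) points excluded and counted separately.
Rotational motion is out of scope (couch yaw is constrained below 0.1°
in the emulated setup, and a single planar view cannot separate
rotations from translations).

## Problem sizes

Full-scale defaults follow the emulated study (0.625 mm voxels, 5°
control points, 3000 apertures, 1190² detector). The packaged
experiments and tests run a reduced configuration chosen to keep a
complete three-arc pipeline within minutes on one CPU: 1.0 mm voxels
(also the smallest spacing at which the 2 mm BB satisfies the ≥2-voxel
sampling invariant), 15° control-point spacing (52 control points),
544² detector at 0.75 mm panel pitch (0.5 mm at isocenter for SID
1500), 300 apertures per control point with a 3×3/±1.8 mm ranking grid,
and an 11×11/±2.5 mm evaluation grid. The closed-loop demonstration
uses 30° spacing (28 points). These sizes are stated in
`bevroi.experiments` and are the package's desk-scale choice; all
physical parameters (arc geometry, aperture range, shift magnitudes,
trace magnitudes) are unchanged from the full configuration.

## Known limitations

- Sub-pixel ground truth is constructed with cubic-spline shifting, and
  the registration samples with the same interpolator; recovery
  accuracy therefore bounds interpolator-consistent error, not the
  error against band-limited truth.
- The MI estimator's peak can sit a few hundredths of a pixel from the
  exact optimum for sparse pixel subsets; dense sampling plus the
  polish stage reduces but does not eliminate this.
- EPID sag, panel response, scatter and MV/kV isocenter disagreement
  are not modeled; anatomy-vs-BB comparisons are therefore free of the
  mechanical error sources a physical measurement would contain.
- The topographic map from a 300-aperture search is noisier than from
  3000; its 60% superlevel set is correspondingly less stable across
  seeds, though the extracted apertures' registration quality is what
  the acceptance checks assert.
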