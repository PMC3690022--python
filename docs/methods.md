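# Methods

## The counting model

A particle qualifies as a countable fiber when three conditions hold
simultaneously: caliper length strictly greater than 5 µm, circularity
4π·area/perimeter² inside [0, 0.663], and pixel area inside user-set bounds.
The circularity interval *is* the aspect-ratio rule: for an ellipse with
aspect ratio α the circularity follows from Ramanujan's first perimeter
approximation,

    C(α) = 4α / (3(1+α) − √((3+α)(1+3α)))²,

which is strictly decreasing with C(1) = 1, C(3) = 0.663, C(7) ≈ 0.333, so
the NIOSH α ≥ 3 rule maps to C ≤ 0.663. Enforcing elongation through
circularity (rather than through the fitted-ellipse axes) mirrors how
particle-analysis software applies the filter; the moments-ellipse aspect
ratio is still measured and reported for diagnostics. The inverse map
α(C) is computed by monotone bracketing + Brent root finding to 1e-12.

The length criterion uses the maximum Feret (caliper) diameter. For solid
ellipses this coincides with the moments-ellipse major axis, but for
rod-like fibers the moments axis overestimates the physical length by up to
15 % (a uniform rod of length L has variance L²/12, giving a moments axis
of 1.155 L), and the caliper diameter is the quantity a human with an
eyepiece graticule would call fiber length.

Interval conventions: length is a strict inequality ("longer than 5 µm"),
circularity and area bounds are inclusive, aspect ratio ≥ 3 is inclusive
via its circularity image.

## Per-tile pipeline

Stages, in order, per tile and per mode:

1. **Background subtraction.** Grayscale morphological opening with a flat
   (2r+1)-square structuring element, then subtraction, clipped at zero.
   The square is separable (two 1-D min passes + two 1-D max passes),
   reducing cost from O(N·k²) to O(N·k); a true disk footprint is available
   behind `PipelineParams.background_footprint` and differs only in corner
   behavior for objects near the element scale. Default radius 25 px — an
   order of magnitude wider than a fiber (3–7 px) and much narrower than
   illumination structure.
2. **Smoothing.** Fixed 3×3 mean filter with edge replication, applied to
   the grayscale image before thresholding (a flag preserves the
   alternative of smoothing the binary mask instead, re-binarized at 0.5).
3. **Local threshold.** Foreground iff intensity > local window statistic
   + offset, window (2r+1)² with r = 15 px, statistic selectable among
   mean (default), median, midgrey. Tracking the local neighborhood makes
   the mask invariant to smooth illumination gradients.
4. **Labeling and measurement.** 8-connected components; per region: pixel
   area, perimeter, second-moment ellipse axes and orientation, caliper
   length, circularity (clamped at 1).

**Perimeter estimator.** Marching-squares sub-pixel contours at the 0.5
level, with closed contours smoothed by a 5-vertex circular moving average
before summing segment lengths. The smoothing removes the staircase bias of
the pixel grid: on rasterized ellipses with axes ≥ 20 px and α ∈ [1, 10]
the resulting circularity is within 1.3 % of C(α), whereas a raw
chain-code perimeter biases circularity by −5…−7 % and a Crofton estimate
by +4…+5 % — both large enough to misclassify particles near the 0.663
boundary. Single-pixel and single-row regions are kept valid by flooring
the minor axis and length at one pixel.

**Default offsets.** Threshold offsets are calibrated to the synthetic
photometry (16-bit scale, fiber amplitudes 8 000–12 000 above background):
4 000 for reflection, 2 800 for fluorescence. Cutting the intensity profile
near mid-height keeps the mask width close to the true fiber width; an
offset far below the peak dilates the mask by ≈ 1 px per side, which for a
short stubby fiber (8 µm × 1.8 µm) pushes measured circularity past the
0.663 cutoff. Real scans with different photometry need these re-tuned —
they are ordinary config, not constants.

## Synthetic slides: what they emulate, what they don't

The generator renders registered reflection/fluorescence tile grids
(default tile 650 × 490 µm at 0.4 µm/px, i.e. 1625 × 1225 px) containing:

- **Chrysotile fibers** — anti-aliased straight capsules, lognormal length
  (median 18 µm, σ = 0.35, clipped to 8–60 µm), width uniform 1.3–2.6 µm,
  visible in both modes (the labeled class).
- **Amosite fibers** — same model scaled by 0.55 (amosite in these
  preparations is much smaller than chrysotile), reflection only.
- **Debris** — filled ellipses, diameter 4–12 µm, aspect ratio ≤ 2.5,
  reflection only.
- **Bubble menisci** — bright annuli with a slightly darkened interior,
  radius 15–35 µm, reflection only. A thin closed ring has circularity
  ≈ (R_out − R_in)/(R_out + R_in) ≪ 0.663 and a long caliper length, so
  rings deliberately pass the elongation filter and reproduce the known
  reflection-mode over-count.
- **Background** — base level plus a directional linear gradient (8 000 ±
  2 000 reflection, 600 ± 150 fluorescence on the 16-bit scale) and
  additive Gaussian noise (σ = 60 by default).

Fiber capsules keep geometric aspect ratio ≥ 4.5: a capsule at aspect
exactly 3 measures C ≈ 0.686 > 0.663 (the capsule is not an ellipse), so
fibers at the class boundary would be systematically rejected; the
asbestos samples the instrument targets are described as predominantly
α ≥ 7, making ≥ 4.5 a realistic floor that keeps the ground-truth classes
separable by the filter. Placement is rejection-sampled: objects stay
inside a single tile (no border crossings; the counter assigns a particle
to the tile holding its centroid) and keep ≥ 12 µm clearance, erroring out
after bounded retries if the scene is too crowded. Both modes share object
geometry exactly (perfect registration). All randomness flows from one
`numpy` Generator seeded by `SceneParams.seed`, so regeneration is
bit-identical.

Not modeled: fiber curvature and bundling (capsules are straight; curved
bundles can split or self-overlap in real scans), optical PSF and
defocus, shot noise and sensor gain, stage registration error between the
two passes, overlapping/touching objects in the default scenes
(generatable, but excluded from validation scenes), and sub-resolution
fibers below the pixel scale. Passing the synthetic validation therefore
demonstrates the correctness of the segmentation-measurement-counting
chain under resolvable, well-separated conditions — not detection
performance on real slides, where contrast, focus and morphology dominate.

## Dilution series and calibration

A serial dilution is emulated by drawing each slide's object counts
Poisson around (base count × dilution factor) — pipetting variability —
with per-slide seeds derived deterministically from a master seed via
`numpy.random.SeedSequence`. The calibration statistic is a least-squares
line through the origin of measured vs. expected counts, slope Σxy/Σx²,
with R² computed against the *centered* total sum of squares (the common
spreadsheet convention for trendlines is uncentered; the centered form is
stricter and is what is reported here). Following the replicate-averaging
reporting convention, each concentration level is averaged over all its
replicate slides (across pooled independent series) before the fit; the
validation series uses 4 levels (factors 1, 0.5, 0.25, 0.125), base 80
fibers/slide, 3 replicates per level and 10 independent master seeds, a
problem size chosen to keep the full run around a minute on one core.
Counts recovered by the pipeline on these slides equal the generated
ground truth exactly, so the residual scatter in the fit is the Poisson
sampling itself.

The automatic-vs-manual bias report is the same through-origin fit of
automatic on manual counts, expressed as (slope − 1) × 100 %.

## Densities, concentrations, bead QC

Fiber density is count/(n_tiles × tile area) in f/mm². Concentration in
f/cc follows the filter-count convention density × effective filter area /
sampled air volume; both constants are survey-specific required inputs
with no defaults. The theoretical bead number per mL of a QC suspension is
6C·10¹²/(ρπ∅³) (C g/mL, ρ g/mL, ∅ µm) — concentration divided by the mass
of one bead. Bead fields for QC are rendered as Gaussian spots whose FWHM
equals the nominal bead diameter, at a Poisson-drawn count.

## Scan plan

The stage raster uses steps of 650 µm (x) and 490 µm (y) — the
display-window size, so tiles abut without overlap — with tiles per axis
given by the ceiling of extent/step and serpentine ordering by default
(consecutive positions always differ by one step along one axis; plain
raster by flag). The registered second pass revisits identical positions.
One tile is 0.3185 mm², ≥ 40× the 0.00785 mm² PCM field. A nominal
5 × 5 mm extent gives 8 × 11 = 88 tiles; the tile count is always derived
from the configured geometry, never hard-coded.

## Numerical and degenerate-input choices

- Circularity from discrete measurements is clamped to ≤ 1.
- Inverse of C(α) brackets upward by doubling, then Brent to 1e-12.
- Single-pixel regions: minor axis and caliper length floored at 1 px.
- Empty slides: the chrysotile fraction is undefined (None), never 0/0.
- Through-origin regression requires ≥ 2 points and some nonzero x; an
  all-zero response returns slope 0 with R² defined as 1 when residuals
  are also zero.
- Background radius larger than the tile is an error; a dilution factor
  sequence must be positive and descending.
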