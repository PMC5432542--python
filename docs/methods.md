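# Methods

## Problem and pipeline

Wheat plant density at emergence is estimated from RGB images of sowing
rows. The pixel-level signal (green vs soil) is easy; the hard part is
that seedlings overlap along the row, so one connected component of the
vegetation mask may hold zero, one, or several plants. The pipeline
therefore separates *where the crop is* (segmentation, rectification,
row detection) from *how many plants each blob holds* (a trained
regression on blob morphology), and only then divides by the sampled
ground area.

## Segmentation

RGB is decoded as sRGB (D65 white, standard gamma) and converted to
CIELab; the a* (green–red) channel separates plants (a* ≈ −30 for
healthy green) from soil (a* ≈ +10). The Otsu threshold is computed on
a 256-bin histogram stretched over the observed a* range; vegetation is
the class strictly below the threshold. Two numerical details:

- **Plateau ties.** When the two a* modes are widely separated the
  between-class variance is exactly flat over every cut inside the
  empty gap. The threshold is the midpoint of the arg-max plateau
  (detected with a 1e-12 relative tolerance), the convention of the
  classical toolboxes; taking the first maximizer would pin the
  threshold to the edge of the gap.
- **Degenerate input.** A constant a* channel raises a typed error
  carrying the constant, rather than guessing a class.

## Rectification

A chessboard on the soil calibrates a projective map H: image px →
ground mm. Interior corners are found by an X-corner saliency filter
(|A+D−B−C| minus the L-corner penalties |A−D| and |B−C| over the
diagonal neighbour quadrants, at two scales), anchored to the lattice
through the four outermost detections, matched one-to-one, and refined
to sub-pixel. H is a normalized-DLT least-squares fit; on rendered
boards the reprojection error is below 0.1 px. Manual corner files are
accepted where detection fails — corner detection is commodity
machinery, not the contribution. Images are remapped onto a regular
ground grid (default 0.5 mm/px here, configurable; masks and label
rasters nearest-neighbour, RGB bilinear), with out-of-source pixels
flagged invalid. Lens distortion is out of scope: the map is purely
projective.

## Row detection

Boundary pixels of the mask (foreground pixels with a background
8-neighbour — on a binary raster this *is* the thin edge set an edge
detector would supply) vote into a Hough accumulator with θ ∈ [−90°,
90°) in 0.1° steps and ρ ∈ (−3000, 3000) px in 1 px steps, ρ =
x·cosθ + y·sinθ. Each point votes once per θ column, so column sums
equal the point count — a conservation law the tests exploit. Points
are recentred about their centroid before voting (a pure ρ shift) so
large frames stay inside the ρ range, and are subsampled to a cap
(default 25 000) for speed.

θ_row is the column whose vote histogram has maximal variance; parallel
rows pile votes into a few ρ bins. Two robustness refinements, both
measured on the generator: (i) the variance is first computed on
columns blurred along ρ (σ = 10 px) — crop rows are vote *bands* as
wide as the plants, whereas the parallel edges of erect leaves create
narrow spurious spikes near the perpendicular orientation that dominate
raw variance at low plant density; (ii) the exact bin is then re-picked
by unsmoothed variance within ±1.5° of the coarse optimum. Ties break
toward |θ| = 90° (rows are near-horizontal by acquisition design).
Orientation precision is limited by row length over band width; with
~1 m rows the true angle is recovered to one 0.1° bin across the full
angle range.

Row offsets are prominent peaks of the θ_row column: smoothed (σ = 8 px),
thresholded at a fraction of the column maximum, accepted greedily in
decreasing height with a minimum mutual distance of 0.6 × the expected
row spacing (known from sowing). The pipeline threshold is 0.15 × max:
per-row vote mass fluctuates (Poisson plant counts, leaf-size spread),
and 0.3 × max was observed to drop genuinely present weak rows, while
the separation rule already makes spurious peaks between accepted rows
geometrically impossible. The raster is then rotated by (90° − θ_row)
mod 180 about its centre so rows are horizontal, and offsets are
re-estimated in the rotated frame with a single-column vote. Objects
attach to the row line nearest their centroid (ties to the lower
index).

## Objects and features

8-connected components of the rotated mask become objects; components
below 4 px (resampling specks) are dropped, and objects touching the
lateral border are flagged. Features F1–F13: pixel area, filled area,
convex area, solidity, extent, equivalent diameter, the
moment-equivalent ellipse (major/minor axis, eccentricity, orientation
in (−90°, 90°], counterclockwise from horizontal), and skeleton length,
end points and branch points. The ellipse uses normalized second
central moments with the +1/12 per-pixel variance term, so a 1×10 bar
has major axis 4√(100/12) ≈ 11.55 px — the convention of the classical
regionprops implementations. Skeletons come from topology-preserving
thinning; because thinning variants differ at the pixel level, tests
assert topology and point counts, not pixel identity. Skeleton point
degree is the crossing number (number of neighbour runs around the
8-ring): ends have degree 1, branch points degree ≥ 3. A raw
≥3-neighbour count would misreport the four pixels flanking a simple
crossing as extra branch points.

## Counting network

Plants-per-object is regressed by a one-hidden-layer network: k_n tanh
hidden nodes, one linear output, inputs z-scored per feature, target in
plant units. k_n defaults to 2 (the architecture consistently selected
by the reference experiments; `select_architecture` re-runs the 1–10
search by cross-validated RMSE, ties to the smaller net). Weights are
fitted by batch L-BFGS on the mean squared error, 200 iterations, small
L2 penalty (1e-4), deterministic per seed. A quasi-Newton batch
optimizer with a fixed budget replaces per-epoch validation early
stopping, which is an idiom of stochastic-gradient training and has no
natural analogue in a deterministic batch fit. Predictions are
continuous expected counts — the average probability over discrete
counts — clipped at 0, never rounded; null objects (count 0) stay in
training.

Feature selection is true recursive elimination (re-ranked after every
drop, not rank-once): importance(j) = Σ_h |W1[h,j]|·|w2[h]|; at each
subset size the mean held-out RMSE over five 90/10 splits is recorded;
the chosen size is the smallest with RMSE < 1.02 × the minimum over all
sizes; the final model retrains on that subset. All subset sizes are
scored on the *same* splits (common random numbers): with independent
splits the ±8 % sampling noise of a 10 % test fold would swamp the 2 %
tolerance band and turn the subset choice into a lottery.

## Density aggregation

Density = Σ continuous counts of objects on counted rows (centroid
rule for the segment window) ÷ (segment length × row spacing × rows
counted). Row spacing comes from the sowing protocol, not from the
detected peaks; rows detected without objects still contribute area. A
central-rows mode (`rows_counted=2`) mirrors reference counting
protocols restricted to the two centre rows. With exact per-object
counts substituted for predictions, the identity estimate ≡ truth holds
to machine precision on every synthetic scene — the aggregation carries
no hidden normalization.

## Synthetic scenes

The generator emulates orthorectified views of wheat at the 1–2 leaf
stage. Per row (default 5 rows at 175 mm): plants placed by a
homogeneous Poisson process at linear density = sowing density ×
emergence rate (default 0.9) × row spacing; each plant has 1–2 leaves
(two with probability 0.6), rendered as tapered quadratic curves,
length 20–60 mm, width 1.5–3 mm, tilted from image-up by N(15°, 10°)
with random sign — the oblique-view projection of erect leaves. Soil is
brown with smooth mottling, grain, and occasional bright stones
(positive a*, never segmented). Plant colour is green with per-plant
brightness/tint jitter chosen so segmentation recall stays ~1; a
`hard_mode` shifts plants toward soil colour. Distractors (greenish
residue/stone blobs that *do* segment) are injected at a rate targeting
the configured null-object fraction (default 0.15, the mid of the
reported 10–20 % range), using a Poisson clustering estimate of the
expected object count (plants × exp(−λ·w), along-row footprint w =
12 mm). Overlap between plants — and hence the right-skewed
plants-per-object distribution with mode 1 — emerges from the Poisson
placement, not from an imposed histogram.

Ground truth is exact: a per-pixel plant-id raster is carried through
the *same* rectification and rotation as the mask (nearest-neighbour),
and each plant is assigned to the object holding the majority of its
pixels, so Σ per-object counts = rendered plants, every seed, every
density. A plant split in two by the pipeline credits its larger part,
and the severed fragment becomes a null object, mirroring how split
plants arise in real imagery. Scenes are byte-reproducible per seed;
an optional known homography renders the 45° oblique view so the
calibration path is exercised end to end.

What the generator does **not** model: illumination fields (flash,
direct sun, shadows), RAW-vs-JPEG compression artefacts, cultivar-
specific leaf shape, weeds, and wind blur. Passing tests therefore
demonstrate the pipeline's correctness and its statistical behaviour
under controlled overlap and null-object regimes, not robustness to
field radiometry.

## Benchmark protocols and problem sizes

`wheatdensity.benchmarks` fixes the evaluation experiments: scenes use
5 rows × 175 mm × 0.5 m segments at 0.5 mm/px with ±1.5° row-angle
jitter; the end-to-end benchmark trains on 50 scenes cycling sowing
densities {100, 200, 300, 400, 600} seeds·m⁻² and scores 30 disjoint
scenes; the per-object benchmark pools 40 scenes at 100–300 seeds·m⁻².
These sizes give a few thousand labelled objects — comfortably above
the few hundred per site used in field practice — while keeping a full
run in minutes on one CPU. All randomness (scene seeds, splits, weight
initialization) derives from a single seed.

## Known limitations

- The variance-of-ρ orientation criterion degrades for very short rows
  or extreme aspect ratios (narrow-axis projections inflate variance);
  the smoothing/refinement above mitigates but does not remove this.
- Per-object counting accuracy degrades as objects grow (high density):
  large merged objects are rarer in training and their count is
  intrinsically more ambiguous. In the end-to-end *relative* density
  error this is partly masked at the scales used here, because
  low-density scenes carry larger Poisson sampling noise per scene.
- Site-specific training is the default; transferring a trained network
  across acquisition setups is untested here.
- Weed/plant discrimination and vegetation indices other than the a*
  threshold are out of scope.
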