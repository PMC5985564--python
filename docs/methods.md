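# Methods

## The measurement model

A root cross-section is treated as a simple closed region with a marked
center `C` and an automatically segmented outer contour. The quantity of
interest per droplet is its *relative distance*

    pp = 100 · r_CD / r_CE ∈ [0, 100],

where `r_CD` is the center-to-droplet distance and `r_CE` the
center-to-edge distance along the droplet's own polar angle. Both
distances use the same angular convention (the printed arccos form covers
[0, π] only; it is extended to [0, 2π) by the sign of `y_mod`, and since
droplet and edge angles share the convention, any consistent choice
yields the same `pp`). `pp` is invariant under translation, rotation and
uniform scaling of the whole slice, which is what makes slices of
different diameters comparable.

Coordinates are 0-based pixel indices, origin top-left, x rightward,
y downward; no axis flip is applied (angles are only ever compared
between droplet and edge, so the flip would cancel).

### Ray casting and non-star-shaped contours

`r_CE` comes from exact ray/segment intersection of the center ray with
every polygon edge. Real slices are often oval or have coves, where a ray
can cross the contour more than twice; the **farthest** intersection is
used, which keeps `pp` monotone in `r_CD` along a ray and bounded by 100
(a droplet sitting radially inside a cove mouth gets `pp < 100`).
Droplets marginally outside the contour — a segmentation halo effect —
clamp from (100, 105] to 100 with a warning; `pp > 105` raises an error,
since it signals a wrong center/edge pairing rather than a halo.

### Classes and areas

`pp` is binned into nine equal-width classes,
`class = min(⌊pp·9/100⌋, 8) + 1`: half-open intervals with the top class
closed at 100. Published interval limits of the form "[11.11–22.21%)" are
rounded prints of multiples of 100/9; exact boundary values belong to the
upper class. Class *areas* are measured pixel-wise: every pixel center
inside the contour polygon receives its own `pp` (against a 2048-point
angular profile of `r_CE`, linearly interpolated) and is tallied into its
class; areas in mm² are pixel counts × (scale/1000)². This matches how
mask areas are measured from images and is robust to concavities, unlike
polygon shrinking. The per-class pixel counts partition the interior
exactly. Rasterization uses a 0.2 px polygon simplification, which
perturbs areas far less than pixel-center binning itself.

## Segmentation

Droplets: 8-bit conversion (green channel of RGB by default, since the
droplets fluoresce green; ITU-R 601 luminance available), median filter
(disk radius 1), grayscale dilation (disk radius 1), Huang–Wang
fuzzy-entropy threshold, 8-connected components, particle filters.
Defaults: minimum area 5 px², unbounded maximum, circularity band
[0.3, 1.0] with circularity = 4π·area/perimeter² using the Crofton
(anisotropy-corrected) perimeter and clipped to 1 (small rasterized disks
nominally exceed 1). All values are configurable; the classical recipe
names the filters but not their radii or cutoffs, so the defaults are
deliberately mild.

The Huang threshold minimizes the total Shannon fuzzy entropy of
memberships `u(g) = 1/(1 + |g − μ_side|/C)` over all split levels, `C`
being the dynamic range; ties take the lowest level (deterministic; note
a two-spike histogram has zero entropy at every candidate, so the lowest
level — which still separates the spikes — is returned). In the pipeline
the droplet threshold is computed **within the tissue region**: composed
slice images carry a large exactly-black mounting frame, and a
three-mode histogram (frame / tissue autofluorescence / droplets) makes
the whole-frame criterion split frame-vs-tissue instead of
tissue-vs-droplets. `binarize_droplets` accepts the tissue mask as an
optional `roi`; without it, behavior on frameless images is the plain
whole-histogram threshold.

Tissue/edge: median filter (disk radius 2), lower cut of a three-class
multi-Otsu (frame / tissue / droplet highlights; a fixed threshold can be
configured), largest connected component, hole filling, outer boundary
via marching squares. The contour is returned counter-clockwise (positive
shoelace area in the pixel frame) with ≥ 16 vertices, first vertex not
repeated. Whether the biological outer boundary is the exodermis or the
outermost visible pixel is not knowable from the images; the outer
boundary of the largest segmented region is used.

The slice center is read verbatim from a sidecar CSV (`slice_id,x,y`),
never snapped; out-of-bounds or missing annotations raise errors naming
the slice.

## Statistics

- Class-count (and class-density) distributions: factor levels are
  treatments, the nine classes are blocks, on the level-mean class
  vectors. ≥ 3 levels → Friedman chi-square (mid-ranks, tie correction);
  2 levels → paired Wilcoxon signed-rank, zero differences dropped, exact
  null for n ≤ 25 when untied (a rank-sum variant is available by
  config). The exact blocking layout of the original analysis is not
  published; this choice reproduces its routing of 2-level factors to
  Wilcoxon and ≥3-level factors to Friedman and is documented as ours.
- Per-slice total densities: one-way fixed-effects ANOVA (two levels:
  pooled t test, so F = t²; Welch optional), levels with < 2 slices
  excluded with a warning; degenerate all-equal input is guarded to
  F = 0, p = 1.
- Post hoc: Student–Newman–Keuls stepwise studentized-range procedure at
  α = 0.05, harmonic-mean n of the two extreme groups for unbalanced
  designs, non-significant stretches shielding their sub-stretches;
  output as a compact letter display.
- Significance is α = 0.05 everywhere; p values are reported raw, with
  no correction across factors (matching the original battery).
- Summary tables report the sample (n−1) SD; displayed means are rounded
  half-up; all computation is in full precision. A single-slice level
  reports SD 0 with an explicit flag.

Standard tests are delegated to scipy.stats; the SNK procedure and the
Huang threshold have no scipy/statsmodels/scikit-image implementation and
are written here. Tests cross-check Friedman against a hand-ranked and a
permutation oracle, Wilcoxon against exact sign-pattern enumeration, and
SNK against frozen studentized-range table values.

## Synthetic data

`SyntheticSliceSpec` defines the study conditions the test-bed emulates:

- Contour: `r(θ) = R·(1 + Σ_{j=2..6} a_j cos(jθ + φ_j))`, default
  R = 300 px, amplitudes (0.08, 0.05, 0.03, 0, 0) — oval-to-irregular but
  star-shaped (Σ|a_j| < 0.35 enforced), sampled at 1440 angles.
- Droplets: per class k a Poisson(λ_k) count; angle uniform, `pp` uniform
  within the class interval, minimum center separation 2·max radius by
  rejection. Default λ = (1, 3, 12, 17, 22, 28, 35, 42, 120): a nearly
  droplet-free central cylinder (classes 1–2), counts rising through the
  parenchyma, and 120/280 ≈ 43% of droplets in class 9 — the magnitude
  and shape of the published distribution (~280 droplets per slice).
- Rendering: tissue autofluorescence 20/255 inside the contour over a
  black frame; droplets as Gaussian-profile bumps (σ = radius/2, peak
  255) clipped to the tissue support, so thresholding is nontrivial;
  Gaussian sensor noise (SD 8) and sparse salt pixels (2×10⁻⁵) over the
  whole frame. Default scale 2 µm/px is a plumbing value for area units —
  the real calibration must come from metadata, and densities are only
  comparable across slices sharing a correct scale.
- Determinism: one seeded generator per slice; batch slices derive seeds
  by fixed offsets from the base seed. Identical spec + seed gives
  bit-identical images.

What the generator does **not** emulate: cell-wall texture, vignetting,
tile seams from manual mosaicking, droplet size gradients, or spectral
bleed-through. Passing tests therefore demonstrate the correctness of the
geometry, binning, aggregation and statistics, and the robustness of the
segmentation to noise, blur-free Gaussian droplets and an irregular
frame — not performance on real tissue texture.

One rendering interaction is worth knowing: at the minimum separation of
2·max radius, two Gaussian droplet profiles bridge at ≈ 69/255 between
their peaks. Sensor noise raises the Huang threshold above that bridge;
in *noiseless* renders the threshold drops below it and ~4% of droplets
merge pairwise into single detections. Class agreement among detections
stays ≥ 99%; recall floors are asserted separately.

## Numerical choices

- Ray/segment intersection tolerances: segment parameter s ∈ [−1e−9,
  1+1e−9], ray parameter t > 1e−9; the farthest valid t wins.
- Angular profile of `r_CE`: 2048 samples, periodic linear
  interpolation; errors are far below the class width for contours of
  the smoothness produced by the generator bound.
- A droplet exactly at the center has an undefined polar angle but a
  well-defined `pp = 0` (class 1); `map_droplets` special-cases it.
- Polygon validity: shapely cleanup (`buffer(0)`) for rasterization
  self-touches; the center must lie strictly inside.
- Connectivity: 8-connected droplets (implying 4-connected background),
  the standard pairing avoiding topological paradoxes.
- Problem sizes in the test-bed (30-slice acceptance batches at native
  768 px scale, reduced 256 px slices with proportionally reduced λ for
  unit tests) were chosen to keep statistical checks at ≥ 3 SE
  sensitivity while the whole suite stays fast.

## Known limitations

- Tile seams and uneven illumination of real composed images are not
  modeled; on real data the tissue threshold may need the fixed
  override.
- The farthest-intersection rule for coves is a documented choice, not a
  reconstruction of the original analysis (which did not state one);
  droplet tables flag nothing for multi-intersection rays beyond the
  geometry itself.
- Densities depend quadratically on the µm/px scale; the metadata column
  is required and never defaulted.
- The Friedman/Wilcoxon blocking operates on level-mean class vectors;
  per-slice resolution within blocks is deliberately not used.
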