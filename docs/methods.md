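# Methods

## Scope and data model

The pipeline operates on calibrated 2-D grayscale rasters (`GrayImage`:
float intensities nominally in [0, 1], `pixel_size` in μm/px). Label masks
use a fixed vocabulary — background 0, tubule 1, spheroid 2 — serialised as
indexed PNG with a fixed palette so classes can never be remapped silently.
All areas are pixel counts × pixel_size²; all lengths are chamfer sums ×
pixel_size.

## Illumination correction

Bright-field frames acquired off-centre carry a smooth dark-to-bright
gradient. The correction models that gradient as a bivariate polynomial of
total degree 4 (15 monomials x^i y^j, i + j ≤ 4) over coordinates normalised
to [−1, 1] per axis — normalisation keeps the Vandermonde system
well-conditioned at any resolution. The chain:

1. **Downsample** by an area-preserving factor (default 0.25; a 3488×2616
   acquisition becomes the 872×654 working frame; pixel size scales by 1/f).
2. **Entropy mask.** Per-pixel Shannon entropy (base 2) of the intensity
   histogram in a 9×9 window, intensities quantised to 256 bins, window
   reflected at borders. Cellular texture is high-entropy; smooth background
   is not. The threshold is Otsu's method on the entropy map by default,
   with a numeric override reproducing a manual-threshold workflow. A
   constant entropy map yields an empty mask (nothing to exclude).
3. **Disc closing** (radius 8 px) fills holes inside the cell mask. Closing
   is computed on the infinite plane — the mask is padded by two radii with
   background before dilate/erode and cropped after — which makes the
   discrete operator exactly idempotent and independent of any library
   border convention. Disc rasterisation: a pixel belongs to the structuring
   element iff its centre is within the radius.
4. **Boundary fill.** Each masked region is replaced by the discrete
   harmonic interpolant of its boundary values — the fixed point of
   repeatedly averaging each filled pixel with its 4-neighbours — solved
   directly as a sparse Dirichlet problem. By the discrete maximum principle
   every filled value lies within the range of that region's boundary
   values; background pixels are untouched. A mask covering the whole frame
   has no boundary data and raises.
5. **Fit and subtract.** The cell-free background is least-squares fitted to
   the degree-4 basis; the fitted surface is subtracted from the working
   image and its mean re-added, which preserves the image mean to machine
   precision. Images that are themselves degree-≤4 surfaces are reproduced
   with residual RMS below 1e-6.

## Hierarchical segmentation and annotation propagation

Contour strength is the Sobel gradient magnitude of the Gaussian-smoothed
corrected image (σ = 2 px default, configurable), normalised to [0, 1]; it
is invariant to intensity inversion, so it does not matter whether cells
are darker or brighter than the background. Watershed from the local minima
(4-connectivity) gives a fine base partition; adjacent regions are assigned
a boundary strength — the minimum over their shared boundary of the stronger
pixel of each touching pair — and united in increasing order of that
strength (single-linkage over the region adjacency graph). Cutting the
resulting merge tree at any strength yields a partition, and cuts at
increasing strengths are nested by construction.

Annotations are points or polyline scribbles with class labels, 0-based
pixel coordinates (x = column, y = row, origin top-left). A base region
containing annotation pixels takes their majority class (ties broken
spheroid > tubule > background — the rarer, more compact structure wins).
Every other region inherits a class at the first merge that joins it to a
labelled cluster, taking the assigned class of the specific labelled region
across the triggering boundary. This local donor rule matters: a cluster
that already contains both spheroid and tubule labels (the two structures
touch in co-culture) still propagates the *adjacent* label, not a
cluster-wide majority. Refinement re-runs propagation on the union of old
and new annotations and is idempotent for a fixed union.

Sparse annotations (one point per object) recover ≥ 90% of pixels on
synthetic scenes but under-label thin tubules, whose fragmented interior
regions often reach a background label first; tracing each tubule with a
scribble (the generator's `scribbles=True` emulation of a refinement pass)
raises per-class recall above 90% for both structures. This mirrors the
interactive workflow the method is designed for: annotate, inspect, refine.

## Morphometrics

* **Areas/counts.** Class area = pixel count × pixel_size². Spheroid
  components use 8-connectivity; a `min_area` filter (default off) exists
  because real images contain debris. Mean spheroid area is total/count,
  with `None` (never a number) when no spheroids are present.
* **Skeleton.** The tubule class is thinned with Lee's method, which keeps
  stroke ends (an 11×5 px bar skeletonises to a ~9 px centreline). The
  skeleton is condensed into a graph of junction clusters (pixels with ≥ 3
  skeleton neighbours, 8-adjacent ones merged) and endpoints, then cleaned
  of rasterisation artefacts: terminal barbs and micro-loops no longer than
  about one stroke width (2 × median distance-transform value on the
  skeleton, or an explicit length) are removed, and junction clusters
  connected by a bridge shorter than that are merged. Without this cleaning,
  corner wedges where two strokes meet at a shallow angle produce spurious
  junctions on ~20–25% of random networks; with it, the generating graph's
  degree-≥3 node count is recovered exactly on ≥ 95% of 200 random networks.
* **Length metric.** Chamfer steps: 1 px orthogonal, √2 px diagonal, with a
  diagonal step skipped when its two pixels share an orthogonal skeleton
  neighbour. This metric systematically overestimates the Euclidean length
  of digital straight lines at arbitrary orientations — up to 8.2% at worst,
  ≈ 4.6% averaged over orientations — so skeleton-length comparisons against
  generator ground truth are made on batch means, and the per-scene figure
  should be read with that bias in mind.
* **Statistics.** Two-tailed two-sample Student's t-test with pooled
  variance (a Welch flag exists); significance at p < 0.05. Degenerate
  zero-variance inputs follow the conventions t = 0, p = 1 for equal means
  and p = 0 for unequal means.

## Dose–response

Percent inhibition is (untreated − treated)/untreated × 100 from viability
readouts (scale-invariant; negative values mean growth stimulation). The
4PL curve is fitted in log₁₀ concentration by bounded least squares
(`scipy.optimize.least_squares`, trf) from five deterministic starts with
the midpoint seeded at quantiles of the tested log-dose range; floor and
ceiling are free within [−20, 120]% by default or pinned to 0/100% in the
constrained mode; the Hill slope is non-negative by default so the fitted
curve is monotone. At least four distinct concentrations are required.

The IC50 decision separates fitting from reporting: `estimate_ic50` returns
a number only when the fit converged **and** the observed maximum inhibition
strictly exceeds 50%. A weak inhibitor that plateaus at, say, 44% at the top
dose yields `Ic50Failure(max_inhibition_below_50)` — the midpoint of such a
curve is an extrapolation the data cannot anchor. The boundary case (exactly
50% at the top dose) also fails, by the strict inequality.

## Synthetic scenes

The generator emulates what the analysis assumes about the data, not its
photorealism:

* **Spheroids** — pairwise-disjoint filled ellipses (axis ratio 0.75–1),
  radii drawn uniformly from `spheroid_radius_range` (default 20–60 μm),
  fully inside the frame. Disjointness makes per-spheroid areas sum exactly
  to the class pixel count.
* **Tubules** — strokes of width `tubule_width` (default 8 μm) along the
  edges of a relative-neighbourhood graph over `n_tubule_nodes` uniformly
  placed nodes (minimum separation four stroke widths, so junctions stay
  resolvable after rasterisation). RNG edges meet at ≥ 60°, which matches
  how capillary-like networks branch and keeps the skeleton well-behaved.
  Ground-truth junction count = graph nodes of degree ≥ 3; ground-truth
  length = summed edge lengths.
* **Rendering** — exact point-in-shape rasterisation at pixel centres;
  spheroids take precedence over tubules in the label mask (the compact
  structure occludes the thin one where they overlap). Cells sit at
  `foreground_level` (0.35) on a `background_level` (0.65) field, carry
  i.i.d. Gaussian texture (σ 0.05, the cue for the entropy mask), and the
  whole frame gains a degree-≤4 illumination polynomial plus sensor noise
  (σ 0.01), clipped to [0, 1]. Geometry, texture and noise use separate
  seeded streams, so the label mask and all ground-truth statistics are
  invariant to noise settings, and equal seeds give bit-identical scenes.
* **Timecourse** — geometry is sampled once (with separations sized for the
  final day) and re-rendered per day with spheroid radii scaled so the true
  area grows by (1 + rate) per day, and stroke width scaled likewise for
  tubule area.
* **Dose tables** — triplicate wells per concentration at the five-dose
  design (1 nM – 10 μM), Gaussian noise in percent. Triplicates reflect how
  plate-based viability assays are actually run; a single noisy 5-point
  series carries too little information to pin the midpoint to within 10%.

What the generator does **not** model: real cell texture and internal
spheroid structure, out-of-focus light, tubule width variation and lumen,
touching spheroids, annotation mistakes. Passing tests therefore demonstrate
the pipeline's correctness under its stated assumptions, not performance on
real micrographs — on real data the interactive refinement loop carries the
weight the generator's clean geometry carries here.

## Numerical and reproducibility choices

* Simulation sizes in the test suite (256×256 scenes, 20-scene segmentation
  batches, 200-network junction studies, 100-seed dose simulations) are
  chosen to exercise every contract at desk scale while keeping the full
  suite under a minute of compute.
* CSV output is written at 6 significant digits, making repeated runs
  byte-identical across platforms; every pipeline run emits a manifest
  (config, version, timings, input checksums).
* Merge ties in the hierarchy are broken by region id; multi-start fitting
  uses a fixed start list; no stage consumes unseeded randomness.

## Known limitations

* Branch points and skeleton length on *segmented* (as opposed to
  ground-truth) masks are sensitive to small gaps in thin strokes; a single
  break splits a skeleton and can remove a junction.
* The boundary-strength rule (minimum over the shared boundary) is fragile
  to single weak pixels on an object's rim; dense annotation compensates.
* The 4PL failure rule is deliberately conservative: data plateauing just
  above 50% yields an IC50 whose confidence interval is wide, and the
  package does not currently report interval estimates.
* Pixel size is a free calibration parameter; no magnification metadata is
  read from image files.
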