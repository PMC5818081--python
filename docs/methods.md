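# Methods

## Invasion scoring

The invasion score treats a projected DAPI image as a point process of
invading nuclei around one dominant spheroid body. The procedure is:

1. **Maximum-intensity projection** of the z-stack. Nuclei are assumed
   bright and sparse enough that projection never hides one behind the
   spheroid (cells are, by assay design, outside the spheroid body in the
   xy plane).
2. **Denoise + threshold.** A Gaussian blur of sd `smooth_sigma_um`
   (default 1 µm) precedes thresholding. This is not cosmetic: the
   intensity bridge between two contacting nuclei is only modestly above
   the threshold, and un-smoothed shot noise can sever it on single pixels,
   turning "touching pair" into "two blobs" at random. The threshold is
   Otsu's method by default (parameter-free, well suited to a
   bright-foreground/dark-background DAPI projection) with a fixed-value
   override for saturated or drifting acquisitions. A flat image raises a
   threshold error rather than returning an arbitrary split.
3. **Spheroid identification.** The spheroid is the largest above-threshold
   8-connected component (`spheroid_rule="largest"`); the alternative rule
   `"center"` takes the component containing the image centre, for fields
   of view where a large debris cluster could out-size the spheroid. Its
   unweighted pixel centroid is the distance reference.
4. **Watershed separation of invading nuclei.** The non-spheroid foreground
   is split by marker-based watershed on the Euclidean distance transform
   (EDT). Seed markers are local maxima of the EDT, thinned greedily by
   exact Euclidean distance so that no two seeds are closer than
   `watershed_min_distance_um` (default 6 µm ≈ one nucleus radius). Two
   implementation details matter here:
   * `peak_local_max` suppresses peaks within a *chessboard* window; a pair
     of nucleus cores separated by just over the minimum distance along a
     diagonal would be collapsed to one seed. The disc footprint plus
     greedy Euclidean thinning keeps suppression isotropic.
   * the integer-grid EDT has tied plateau maxima; without thinning each
     tie would seed its own watershed region and shatter single nuclei.
5. **Region gates.** Accepted regions must have area within
   [`min_cell_area_um2`, `max_cell_area_um2`] (defaults 20–400 µm²,
   rejecting debris and unresolvable clumps) and, by default, must not
   touch the spheroid mask (a cell still in contact with the spheroid has
   not invaded "away" from it). Centroids are unweighted pixel-centre
   means, reported in µm with x = (col + 0.5)·px, y = (row + 0.5)·px.
6. **Score.** MSD = mean of squared centroid-to-spheroid-centroid
   distances. With zero cells the score is *absent* (`None`), never 0: an
   empty field and a non-invading spheroid are different results. An
   `edge` distance reference (distance to the nearest spheroid pixel) is
   available for users who prefer boundary-relative distances; the default
   follows the centroid convention because the centroid is what the
   segmentation defines most robustly.

The score is invariant under rigid motions of all centroids and scales as
s² when the pixel calibration scales by s; both are covered by tests.

## Chemotaxis statistics

Per track: accumulated distance = Σ step lengths, Euclidean distance =
|end − start|, direction = angle of the net vector, velocity = accumulated
distance / elapsed time (the convention of manual-tracking tools; a
`velocity="euclidean"` option gives the net rate instead). Population level:
a track counts toward the right/left reservoir by the sign of its net
component along the configured axis (`+x` by default); exact zeros form a
third class reported separately, so the three percentages always sum to
100 — whether "non-movers" belong in a denominator is a reporting decision
left visible to the user rather than hidden.

The Rayleigh test uses one angle per cell (the net-displacement direction;
tracks with zero net displacement carry no direction and are excluded).
With R the mean resultant length and Z = nR², the p-value is the standard
series approximation

p ≈ exp(−Z)·[1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)],

clamped to (0, 1]. At the sample sizes of a tracking experiment (tens of
cells) this approximation is accurate to ~10⁻³ and its empirical type-I
error at α = 0.05 sits inside [0.04, 0.06] (verified by simulation at
n = 60, 10⁴ replicates); an exact permutation test would add cost without
changing any decision.

## Burden metrics

* **Volume:** 0.5236·((width+length)/2)³ mm³ — the ellipsoid approximation
  (0.5236 ≈ π/6) applied to the calliper mean diameter; no further
  correction factor.
* **Burden and nodules:** burden = 100 × tumour pixels / lung pixels.
  Nodules are 8-connected tumour components (8-connectivity matches visual
  counting of contiguous lesions); only components ≥ `min_area_um2`
  (default 1000 µm²) are *counted*, but sub-threshold components still
  contribute to the *area* percentage by default — the two metrics are
  defined independently, and a flag (`include_subthreshold_in_pct=False`)
  gives the stricter variant. Tumour pixels outside the lung are clipped to
  the lung and the violation count is reported.
* **Gel contraction:** 100 × (1 − final area / initial area); expansion is
  reported as a negative value, not clamped.
* **Roundness:** the isoperimetric quotient 4πA/P², clipped to [0, 1]. The
  perimeter is the 4-direction Crofton estimate: a marching-squares contour
  of a rasterised mask is systematically long (staircase bias), which would
  push even a perfect disc's quotient far below 1, whereas the Crofton
  estimator targets the true boundary length (a radius-50 px disc scores
  ≈ 0.99). This quotient is a surrogate for proprietary high-content
  "roundness" channels, which are themselves reported in arbitrary units.
* **Grubbs:** two-sided single-outlier test, G = max|xᵢ − x̄|/s, critical
  value ((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/(2n) Student-t
  quantile on n−2 df. One call flags at most the single most extreme
  point, matching the once-per-dataset screening convention of common
  statistics packages.

## Synthetic data: what it emulates, and what it does not

The generators supply inputs with the statistical structure each stage
assumes, plus exact ground truth.

* **Invasion stacks** (defaults: 640×640 px at 1 µm/px, 3 planes, spheroid
  radius 100 µm, 50 nuclei uniform at 130–280 µm from the centre, noise sd
  0.1 of the unit signal ≈ SNR 10): the spheroid is a uniform bright disc
  present in every plane; nuclei are isotropic Gaussian blobs
  (σ = nucleus radius/2 = 3 µm, truncated at 3σ) each assigned to one
  random plane, so the projection step is genuinely exercised. Blob
  intensities *add* where nuclei overlap, as fluorescence does — this is
  what makes contacting pairs merge into one thresholded component.
  Contacting pairs are planted at 1.5 × nucleus radius separation, close
  enough to merge under plain labelling yet resolvable by the watershed;
  pair members share a z-plane (contacting cells sit at the same depth).
  Non-pair nuclei keep a minimum separation of 4 × nucleus radius so that
  "well-separated" fixtures isolate counting accuracy from clumping.
  Default field/distance scales are plausible for a day-scale collagen
  invasion assay; they are not calibrated to any particular instrument.
* **Tracks** (defaults: 60 tracks, 24 steps of 20 min = 8 h): cumulative
  sums of i.i.d. Gaussian steps plus a constant drift vector. Real
  fibroblast migration is persistent (velocity autocorrelation) and
  gradient sensing saturates; a drifted white-noise walk reproduces only
  the moments the statistics consume (net displacement distribution, step
  moments), which is exactly what makes closed-form checks possible.
* **Lung sections:** an ellipse lung with disjoint disc nodules of
  requested areas placed uniformly at random (largest first, rejection
  sampling). Rendered pixel areas match requests to rasterisation accuracy
  (±~1 pixel-row). No H&E colour or tissue texture is simulated — the
  quantification consumes binary masks, so masks are what the generator
  produces.
* **Gels:** concentric discs with the prescribed area ratio.

Passing tests on these inputs therefore demonstrate correctness of the
*computations* (projection, separation, distances, statistics, filters) on
data satisfying the stated model; they do not certify segmentation
robustness against uneven illumination, optical aberration, nuclear-shape
variation or tissue artefacts, which real acquisitions add.

All randomness in a generator call flows from one `numpy` Generator seeded
by the `seed` parameter; outputs are bit-reproducible per seed, and the
command-line `simulate` subcommands inherit this.

## Numerical choices and degenerate inputs

* Pixel-centre coordinate convention throughout ((col+0.5)·px, (row+0.5)·px),
  0-based, origin top-left; ground truth and recovered centroids share it.
* 16-bit rendering scales the unit signal to 40 000 counts and clips to
  [0, 65535]; a 0.1 background offset keeps additive noise from clipping
  at zero.
* Empty stack, flat image, no-foreground threshold, empty lung mask,
  zero-variance Grubbs sample, < 3 Rayleigh angles, zero-length or
  time-degenerate tracks: all raise typed errors (`ParameterError`,
  `FormatError`, `ThresholdError`, `SegmentationError`) rather than
  returning sentinel numbers. The single deliberate sentinel is the absent
  MSD at N = 0.
* Rejection sampling for nucleus/nodule placement fails loudly after a
  bounded number of attempts when a requested density is infeasible.

## Problem sizes used in validation

The validation suite and the acceptance script use 640×640 px stacks
(20 seeded replicates for recovery), 10⁴ replicates for the Rayleigh and
Grubbs calibration rates, 10³ random tracks for the triangle-inequality
sweep, and a 512×512 lung section; these sizes give Monte-Carlo error well
inside the tested tolerances while keeping a full run in the seconds range.
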