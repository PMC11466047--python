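# Methods

## Striated-lattice image model

The synthetic F-SHG lattice is built from a periodic 1D axial template
over one sarcomere period L: intensity 1 on the A-band (length `aband_um`,
centred at L/2) except a 0 gap of width `mline_um` at its centre (the
M-line, which has no SHG contrast), and 0 on the I-band. The 2D image is
this template extruded perpendicular to the myofibril axis and rotated by
`orientation_deg`; because the pattern is constant perpendicular to the
axis, isotropic Gaussian PSF blur equals a 1D Gaussian convolution along
the axial coordinate, which the generator evaluates in closed form as sums
of normal-CDF differences (no resampling or discrete-convolution error).
The blurred pattern is scaled linearly so its 1D dynamic range maps to
`[background_photons, peak_photons]`, and per-pixel Poisson counts are
drawn with a seeded generator. A `noiseless=True` flag returns the
expected-photon image for oracle comparisons.

Coordinates: pixels are 0-based with the origin at the top-left pixel
centre, x = column, y = row; physical positions are um from that origin;
angles are degrees in (−90, 90] from +x toward +y. Rotation is exact
(analytic evaluation at rotated coordinates).

**Defaults.** Period 1.84 um (mean SL of adult murine left ventricle),
A-band 1.6 um and M-line 0.17 um (vertebrate striated-muscle literature
values; both exposed as parameters), pixel 0.04 um, PSF FWHM 0.25 um, peak
200 photons over background 5. Invariants: 0 < M-line < A-band < period;
pixel ≤ period/4 (striation Nyquist).

**Band regime.** The image is "double-band" when the blurred noiseless
template has a local minimum at the M-line centre whose depth below the
lower flanking maximum exceeds 1% of the template dynamic range, else
"single-band". The depth is measured against the flanking maxima between
the two I-band centres, which is robust to the flat gap floor at
near-zero blur. For the default geometry the double→single crossover sits
near FWHM 0.93 um; at FWHM 0.60 um the M-line dip still holds ~57% of the
dynamic range, so both 0.25 and 0.60 um PSFs produce double-band images.
A genuinely single-band regime needs FWHM ≳ 1.0 um at this geometry. The
crossover is a property of the model geometry, not an empirically anchored
optical constant.

**Noise model.** Poisson only (photon counting); no read noise. This is
adequate for testing estimator robustness at confocal photon budgets.

## Sarcomere-length measurement

Pipeline: orientation estimation → line-profile extraction → minima
detection → minima classification → interval statistics.

* **Orientation** comes from the structure tensor of Gaussian-smoothed
  gradients (default SD 2 px) averaged over the ROI. In a striation image
  the intensity gradient points along the myofibril axis, so the returned
  angle is the orientation of the tensor's leading eigenvector; coherence
  (λ1−λ2)/(λ1+λ2) serves as confidence. A constant ROI is a typed error.
* **Profiles** are sampled at `step = pixel_um` by bilinear interpolation,
  averaging `width_px` (default 5, odd) parallel lines offset 1 px
  perpendicular to the axis. When no line is supplied, the longest centred
  line at the estimated orientation is used.
* **Minima detection** smooths with a Gaussian of SD 0.1 um (default),
  keeps strict local minima with prominence ≥ 5% of the smoothed dynamic
  range (default), and refines each position by parabolic interpolation
  through the minimum and its two neighbours, giving sub-pixel
  localization well below the 0.04 um pixel.
* **Classification** labels each minimum `iband` (retained) or
  `aband_internal` (excluded) by three rules applied in order:
  1. *Prominence split*: 1D Otsu threshold on prominences; the shallow
     class is excluded when the class-mean ratio exceeds 2 (default).
     This fires when M-line dips are much shallower than I-band dips
     (wide PSF near the regime crossover).
  2. *Parity alternation*: when minima are evenly spaced (spacing CV ≤
     0.25) and at least four are present, minima split into two parity
     classes anchored at the most prominent minimum. The off-parity class
     is excluded only if every anchored-parity prominence strictly
     exceeds every off-parity prominence (an order-statistics test with
     no magnitude threshold) *and* the gap exceeds 10% of the median
     prominence. This covers the deep double-band regime, where I- and
     M-minima prominences differ by only ~25–50% — too little for the
     Otsu ratio — yet alternate perfectly; the profile's first and last
     minima are left out of the statistics because their prominences are
     truncated by the profile ends. For a single-band profile the two
     parity classes are draws from the same distribution, so strict
     dominance plus the gap margin is overwhelmingly unlikely to occur by
     chance.
  3. *Periodicity fallback*: if the retained spacings are still irregular
     (CV > 0.25), the dominant period is taken from the biased
     autocorrelation of the mean-subtracted smoothed profile and the
     subset of minima matching that period (greedy walk anchored at the
     most prominent minimum, tolerance 0.3 period) is kept.

  Ties — equal prominences, no periodic structure, fewer than three
  minima — exclude nothing, which is the correct single-band behaviour.
* **Statistics**: lengths are successive differences of retained minima;
  intervals outside the physiological bounds [1.3, 2.5] um (default,
  configurable) are flagged and excluded from the summary rather than
  silently dropped or kept. Mean and SD (n−1) are recomputable from the
  per-interval lengths; `n` counts intervals. Fewer than two retained
  minima or no in-bounds interval yields an n = 0 result with a reason
  code, never an exception. The detected regime is "double" iff any
  minima were excluded as A-band-internal.

A "measurement" here is one inter-minima interval; per-profile and
per-image aggregation granularities are available from the result object.

## Capillarization metrics

For an instance label map with per-label categories, pixel size, and FOV
area (default: full image physical area, overridable per ROI):

* capillary density per FOV = n_cap / FOV area (um⁻²);
* capillary density per cardiomyocyte area = n_cap / Σ cardiomyocyte mask
  area (um⁻²), a typed undefined-result error when that area is zero;
* capillary-to-cardiomyocyte ratio = n_cap / n_cm, a typed error when
  n_cm = 0.

Counts are label-based (instances), never connected components of a
binary union; border-touching labels are counted by default with an
`exclude_border` opt-out. Multi-ROI summaries report mean and SD (n−1)
per metric; undefined ROIs are flagged rows, excluded from the summary,
and never abort the report. A size-threshold auto-categorization helper
exists behind an explicit opt-in; the category table is the contract.

## Tissue-layout generator

Dart-throwing with rejection: irregular convex polygon cross-sections for
cardiomyocytes (12-vertex star polygons, convex hull, radius jitter ±25%)
and discs for capillaries, fully inside the FOV, pairwise disjoint with a
1-px guard ring. Defaults — 6 cardiomyocytes of mean radius 8 um and 5
capillaries of radius 2.5 um in an 80×80 um FOV at 0.2 um/px — give ~20%
area coverage so placement converges in a few hundred attempts; the
budget is configurable and its exhaustion is a typed error suggesting
lower density. The intensity image (textured bright cardiomyocyte
interiors, dark capillary lumens with bright rims, Poisson sampled) is
cosmetic; only masks, categories, counts and areas carry contract weight.
The generator emulates instance geometry and counts, not staining
variability, segmentation errors, or the capillary-rich packing of real
myocardium (~0.8 capillaries per cardiomyocyte at far higher areal
density): passing tests demonstrate metric arithmetic and pipeline
correctness on exact masks, not segmentation quality on tissue.

## Stack processing

* Frame averaging is the pixel-wise float mean; for Poisson-limited
  frames the noise SD falls as 1/√N.
* Gaussian filtering is separable convolution with reflect boundaries;
  σ = 0 is the identity. The Wiener filter is the local-statistics form
  m + max(v−n, 0)/v · (x−m) over a square window (default 5 px), with
  noise power n defaulting to the median of local variances — median
  rather than mean so sparse bright structure does not inflate the noise
  estimate; a noiseless constant image passes through unchanged.
* Drift correction estimates per-frame translations by phase correlation
  with subpixel refinement (local Fourier upsampling, factor 50). Frames
  are mean-subtracted and Hann-windowed before correlation; without the
  window, the FFT's circular wrap-around biases the correlation peak
  toward zero shift on smooth non-periodic fields (observed ~0.4 px error
  on integer shifts, < 0.05 px with it). Estimated shifts are applied by
  bilinear interpolation with reflect padding. Registration against
  `first` uses direct estimates; `previous` composes consecutive-frame
  estimates. A constant frame gets offset (0, 0) and a low-confidence
  flag. Purely 1D patterns (an untextured lattice) constrain only the
  axial shift component — an identifiability limit, not an estimator
  defect; the SL-after-realignment guarantee is unaffected because the
  pattern is invariant along its stripes.
* Binarization: `global` is Otsu on a 256-bin histogram (threshold
  equivariant under affine intensity rescaling); `adaptive` thresholds at
  local mean − offset over an odd square window, so a negative offset
  demands intensities above the local mean and detects compact bright
  spots under shading gradients that defeat any single global threshold.
  Constant images yield an all-background mask with a flag. The chain
  order is fixed (average → filter → align → binarize); averaging
  collapses the stack, so combining it with alignment is rejected as
  contradictory.

## Validation experiment sizes

The recovery experiment uses 160×384 px images (6.4×15.4 um at 0.04
um/px, about 7–10 periods per profile), 9 periods × 2 PSFs × 20 seeds =
360 runs; drift experiments use 6-frame stacks with shifts up to 5 px;
averaging statistics use up to 64 frames of 96×96 px. These sizes give
per-condition Monte-Carlo resolution well below the one-pixel acceptance
tolerance while keeping the full suite and the acceptance script each
under a minute of compute.

## Known limitations

* The lattice generator is 2D and strictly periodic with a spatially
  invariant PSF; real tissue adds curvature, intensity modulation along
  fibres, and depth-dependent aberrations. The classification rule
  tolerates smooth amplitude modulation up to roughly ±20% of the local
  envelope before the parity-dominance test stops firing.
* Drift correction is translational only, matching its contract; it does
  not model structural change between Z-planes.
* The capillarization module measures arithmetic on given masks; it
  cannot detect segmentation or categorization errors upstream.
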