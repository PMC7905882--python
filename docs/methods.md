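# Methods

This note records the models, parameter choices and numerical
conventions behind `stedclust`, including the places where the design
was genuinely open and what the package chose.

## Image model and simulator

A synthetic STED image is the sum of spot profiles plus background,
optionally Poisson-sampled per pixel:

- **Support region**: a star-convex blob — a base radius modulated by
  a random low-order Fourier series (orders 2–7, amplitudes ∝ 1/k) —
  filling 20–70% of the frame. This emulates roughly convex cells with
  protrusions; it does not model filopodia, internal organelle
  exclusions, or partially imaged cells.
- **Point processes**: complete spatial randomness (homogeneous
  Poisson, the null), a Thomas parent–offspring process (aggregation),
  isolated pairs at an exact design spacing (the ligand geometries
  13.6 / 43.5 / 202.3 nm), and coincident multiplets. Pairs get
  isotropic random orientation; a pair is re-drawn if its partner
  falls outside the (optionally margin-eroded) mask.
- **Spot profile**: 2D Lorentzian by default, `A / (1 + r²/γ²)` with
  FWHM = 2γ — self-consistent with the Lorentzian line-profile
  estimator downstream; a Gaussian profile is available for robustness
  checks. Pixel values sample the profile at pixel centres (no area
  integration), adequate at 20 nm pixels: pixel-centre sums match a
  10× finer quadrature within 2%.
- **Per-cluster apparent FWHM**: truncated normal, mean 80 nm,
  sd 20 nm, floor 40 nm — the plausible apparent-size range at
  30–50 nm resolution.
- **Photometry defaults**: 300 expected photons at a spot centre,
  5 per pixel of in-cell background, 0.5 outside the cell, Poisson
  noise. Chosen to give the strong spot-to-background contrast of
  surface-receptor STED data.
- **Seeds**: one master seed; cell *i* uses
  `SeedSequence([master_seed, i])`, with offsets +1 for point sampling
  and +2 for photon noise, so any cell regenerates in isolation. The
  rule is echoed in the dataset config.

The default three-condition study (24 cells each, mirroring a
24 × 3 = 72-cell design) uses a CSR control at 3 clusters/µm² and two
Thomas patterns (0.8 parents/µm², 4 offspring/parent) with offspring
sd 100 nm ("tight") and 200 nm ("loose"). The spreads put the
aggregation above the resolution limit — so member clusters remain
individually localizable — and inside the 200 nm density bandwidth,
the scale where the analyses are sensitive. Cluster densities per cell
are not constrained by real data and were chosen for testability.

What passing tests on this generator do **not** show: robustness to
uneven illumination, scan drift, detector artifacts, out-of-focus
background, or spot shapes beyond isotropic/elliptical profiles. The
generator validates the analysis logic, not the microscope.

## Localization chain

Order: binarize → mask multiply → DoG(σ₁ = 0, σ₂ = 100 nm) → clip at
0 → Gaussian smooth (σ = 15 nm) → standardize by in-cell (mean + std)
→ peak detection above a global threshold → merge adjacent maxima.
All σ values are physical (nm), converted to pixels as σ/pixel_size;
non-integer σ is fine. All Gaussian filtering uses **reflect**
boundary handling, fixed for reproducibility. Standardization uses the
population std (ddof = 0) and zeroes out-of-mask pixels; it makes the
chain exactly invariant to global intensity scaling.

Choices where the procedure was open:

- **Binarization** (operator unspecified): Otsu on the log1p of a
  σ = 50 nm smoothed copy, hole filling, largest connected component.
  On a linear histogram the bright spots dominate Otsu's between-class
  variance and the threshold eats dim cell regions; the log transform
  makes the in-cell vs out-of-cell background modes dominate. With
  spots ≥ 400 nm inside the true boundary, the recovered mask overlaps
  the generating mask with Jaccard ≥ 0.9; spots at the very edge leak
  heavy Lorentzian tails outside the true support and bias any
  intensity-based segmentation outward.
- **Peak merging**: 8-connectivity; merged position =
  intensity-weighted centroid; coordinates in nm with pixel centres at
  (i + 0.5)·pixel_size.
- **Edge exclusion**: detections within 60 nm (≈ one resolution
  length) of the mask boundary are discarded. The DoG of the sharp
  masked edge leaves a positive ridge just inside the boundary; in a
  cell with little or no spot signal, per-cell standardization
  amplifies that ridge above any sensible threshold. A blank cell then
  correctly yields zero localizations.
- **Global threshold**: the original analysis set it per acquisition
  day; there is no universal default. `suggest_peak_threshold`
  calibrates it from synthetic calibration images whose spot content
  matches the batch: it takes 2× the strongest local maximum found in
  blank regions (≥ 200 nm from any true spot). Matching the spot
  content matters because the standardization divisor is dominated by
  spot signal; a spot-free calibration image standardizes its own
  noise onto the wrong scale. A corollary worth knowing: in real cells
  with very few clusters, per-cell standardization raises the noise
  floor and false positives become likelier — a property of the
  standardization scheme itself.

## Cluster statistics

- **Density map**: Gaussian KDE of the localization point cloud,
  bandwidth 200 nm, evaluated on a grid at the image pixel spacing
  (sklearn `KernelDensity` underneath). The map uses unit-peak kernels
  (density × n × 2πbw²) so intensities read as "clusters per kernel":
  one isolated cluster peaks at exactly 1.0, m coincident clusters at
  m. The probability-density normalization differs only by that
  constant and is available via `normalization="density"`. Local
  maxima use the same merge rule as localization, with no
  minimum-separation constraint; numerically empty regions
  (< 10⁻⁶) are ignored.
- **k-NN**: k = 4, self excluded, k·n distances per cell; cells with
  ≤ k localizations are excluded from this analysis with a warning.
  Verified against an exhaustive O(n²) oracle.
- **FWHM**: profiles are sampled every pixel_size/2 by cubic-spline
  interpolation. Bilinear interpolation was measured to flatten
  2–3-pixel peaks and inflate fitted FWHMs by up to ~19% at 50 nm;
  cubic brings the worst case to ~6%, within the ±10% accuracy target
  for noiseless spots of 50–150 nm. Fits start at A = max − min,
  x₀ = argmax, γ = 50 nm, offset = min, with γ bounded to (5, 400) nm;
  a constant profile gets R² = 0 (no peak information); fit failures
  are flagged, never raised. The fit includes a constant offset — the
  in-cell background pedestal would otherwise bias γ upward; the
  minimum-FWHM rule across the four angles reports the narrow axis of
  elongated clusters and trims the residual broadening of off-centre
  cuts. Clusters whose 400 nm profile would leave the image are
  skipped and counted in the run log.

## Curve statistics

Per-cell values become Gaussian KDE curves (Scott's rule per cell by
default; a fixed bandwidth in data units is available to make curves
strictly comparable across cells). The shared evaluation grid spans
the pooled range padded by 3 pooled-Scott bandwidths, 512 points,
clipped at 0 for nonnegative quantities (distances, sizes); each curve
is renormalized to integrate to 1 on the grid, compensating boundary
truncation. A degenerate cell (all values identical) is represented as
a Gaussian bump two grid steps wide. Condition curves are pointwise
means with a t-based CI (normal approximation behind a flag);
non-overlap of two 83.4% bands reproduces a 5% two-sided t test when
the group standard errors are comparable (null non-overlap rate
0.051 vs t-test 0.051 at 10,000 replicates, 24 cells per group) and is
conservative when they are not.

Two summary locations are kept distinct: the location of the largest
mean-density difference (peak of |Δ|) and the crossover point (peak of
the running integral of Δ, coinciding with a sign change of Δ); ties
break toward the smaller value. The one-sided two-sample KS test of
"A is bigger than B" uses D⁺ = sup(ECDF_B − ECDF_A); p-values are
exact for small samples and asymptotic for large ones (scipy's auto
rule) — at n ≤ 8 the asymptotic formula visibly disagrees with the
exhaustive permutation distribution, the exact path matches it.

## Validation experiments and problem sizes

`stedclust.validation` re-derives headline quantities end-to-end:
pair-spacing recovery (100 images, one 202.3 nm pair each, 60 nm
spots, 300 peak photons, Poisson noise; mean recovered distance
≈ 203 nm, sd ≈ 9 nm), resolution behaviour (200 pairs per spacing:
13.6 nm pairs localize as one cluster, 202.3 nm as two, ≥ 95% each)
and the CI-overlap null calibration above. The test suite runs the
full 3 × 24-cell study at 256 × 256 pixels and 20 nm pixel size —
sizes chosen so the whole suite completes in about a minute while
keeping ≥ 30 clusters per typical cell.

## Known limitations

- Per-cell standardization is unstable for nearly empty cells (few or
  no clusters): noise is amplified to order-1 standardized values.
  Real studies sidestep this because imaged cells carry abundant
  receptor signal; the pipeline logs rather than repairs such cells.
- The density-peak analysis reports all local maxima of the KDE map;
  in sparse regions, low-intensity saddle maxima are genuine maxima of
  the map and are not filtered.
- FWHM sizing assumes approximately Lorentzian, mostly isotropic
  spots; strongly non-elliptical or overlapping clusters bias the
  minimum rule downward.
- The CI-overlap rule is pointwise; no multiplicity correction is
  applied across the grid, matching its role as a descriptive
  significance band rather than a family-wise test.
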