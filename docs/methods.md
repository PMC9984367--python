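# Methods

This note records the models, conventions and numerical choices behind
`grainmorph`, in the order the pipeline applies them, together with what
the synthetic validation does and does not demonstrate.

## Images and binarization

Micrographs are treated as scalar height fields: grayscale intensity is
normalized by bit depth to [0, 1] and tagged with a user-supplied pixel
scale in µm/px. Vendor SEM TIFF tags are not parsed — they are not
standardized across instruments — so the scale is always an explicit input.
Binarization defaults to Otsu's between-class-variance threshold with the
polarity convention *brighter = solid phase*, matching the backscatter
appearance of starch and protein; both the threshold and the polarity are
overridable, and a constant image with the automatic method is a hard
error rather than an arbitrary mask.

## Minkowski functionals

On a binary map with `N` pixels of which `N_w` are white, the package
reports the solid share `V = N_w/N·100 %`, the boundary share
`S = N_bound/N·100 %`, and the Euler–Poincaré characteristic
`χ = (C_w − C_b)/N` (also on the conventional ×10³ display scale).
Conventions the literature leaves open were fixed as follows:

- `N_bound` counts **unordered 4-adjacent white/black pixel pairs**. It is
  not clamped: a checkerboard yields `S = 150 %`, which is flagged in the
  API docs as a pathological input rather than silently truncated, keeping
  the formula literal.
- Connected components use the standard complementary pair that avoids
  topological paradoxes on the square lattice: white 8-connected, black
  4-connected. With this pair, `k` disjoint granules on a plain background
  give `C_w = k`, `C_b = 1` exactly.

All counts are exact integers before any division; a brute-force
double-loop oracle (including BFS component counting) verifies exact
agreement on random images in the test suite.

## Granule segmentation and typing

Touching granules are split by a watershed on the negated Euclidean
distance transform, seeded at distance-transform maxima at least
`min_distance_px` apart (default 3 px, one seed set per connected
component). Components too small to host a peak keep their component
label, so labels always partition the foreground exactly.

Granule cross-sectional areas (pixel count × pixel scale²) classify into
the standard wheat starch classes: type A above 177 µm², type C below
20 µm², type B in the closed band [20, 177] µm². The cutoffs are the
circle areas at equivalent diameters 15 µm and 5 µm rounded to integers;
the closed band resolves the otherwise unassigned boundary points. The
coverage rate is the granule count divided by the imaged area.

## Texture: anisotropy and fractal scaling

The autocorrelation is computed by FFT (circular, mean-removed,
variance-normalized); an optional Hann window suppresses edge leakage on
real, non-periodic micrographs and is off for synthetic periodic fields so
their ground truth stays analytic. Along each of 72 directions (2.5°
steps over the half circle) the radial lag where `R` first decays to 0.2
is located by bilinear interpolation along the ray and linear
interpolation between samples; the texture aspect ratio `Str` is the
fastest decay length over the slowest, so `Str ∈ (0, 1]` and 1 means
isotropy. (Defining the ratio the other way around would exceed 1; the
orientation used here matches the convention that reported values lie in
(0, 1].) If the central lobe never reaches the threshold inside the map —
long-range correlation relative to the field of view — the ratio is
undefined and the library raises; the pipeline records it as missing.

The structure function accumulates squared height differences for integer
axis-aligned offsets along rows and columns, binned by lag, for lags from
1 px to a quarter of the short side (half for corner-lag studies). This
profile-based estimator is exactly reproducible by a brute-force double
loop, which the tests exploit. `Sq` is the RMS of the mean-subtracted
heights; the corner scale length `τ_c` is the first lag where `S(τ)`
reaches the plateau `2S_q²` (linear interpolation), with a
`converged=False` flag when the plateau is never reached.

The monofractal fit is a least-squares line on (log τ, log S) over
`τ ∈ [2 px, min(τ_c, τ_max)/2]` — above single-pixel noise, below the
plateau shoulder; at least 6 lags are required. With slope `α`, the
reported surface dimension is `D = 3 − α/2`, which lies in (2, 3) for
physical surfaces (a self-affine surface of Hurst exponent `H` has
`α = 2H`, `D = 3 − H`). The raw slope is stored alongside so the profile
convention `D_p = 2 − α/2 ∈ (1, 2)` can be audited; fits with `α` outside
(0, 2) are flagged `accepted=False` rather than clipped. `K = exp` of the
intercept, in units of `S` at τ = 1 µm; heights scaled by `c` scale `S`
and `K` by `c²` and leave `D`, `Str`, `τ_c` unchanged.

**Monofractality test.** A structure is declared monofractal when, within
the fit range, every log10 residual stays within 0.15 decades and the
quadratic coefficient of a second-order log-log fit stays within 0.25 in
magnitude. These defaults were set from the sampling behavior of genuine
self-affine fields: at 512², finite-field fluctuations alone produce
residuals up to ≈0.10 decades and spurious half-range slope differences up
to ≈0.37, so stricter cutoffs (or a split-slope criterion) would reject
truly monofractal surfaces, while genuine two-regime mixtures bend far
more (residuals ≥ 0.18, curvature ≥ 0.24 for well-separated regimes).

## Kernel geometry

`D_m = (LWT)^{1/3}`, `R_s = P²/(4πA)` and `R_c = 2√(πA)/P` satisfy
`R_s·R_c² ≡ 1`; the isoperimetric inequality (`R_s ≥ 1`) is enforced on
input and a violation is reported as inconsistent measurement. Silhouette
measurement uses the four-direction Crofton perimeter estimator — naive
pixel-edge counting overestimates smooth perimeters by ~11 %, while
Crofton lands within 2 % of the analytic value for convex shapes at the
resolutions used — and the major/minor axis lengths of the
second-moment-matched ellipse. Descriptors computed from group-mean
L, W, T approximate but do not equal the mean of per-kernel descriptors;
worked-example checks therefore carry a ±0.01–0.02 tolerance, the rounding
scale of the printed inputs.

## Milling energy, particle size, DSC

`E_r = (E_c − E_s)/m_g` with the idle energy `E_s` = idle power × milling
time; `E_c < E_s` is rejected as inconsistent. PSD percentiles come from
the cumulative volume curve evaluated at bin centers with the midpoint
convention and interpolated **against log size** (the laser-diffraction
convention; a linear axis is a flag away). `d_avg = Σ φ_i d_i` is the
volume-weighted arithmetic mean. SPAN is scale-invariant by construction.
DSC endpoints are bookkeeping only (no thermogram integration): the end
temperature is canonicalized to `T_e` (some instrument reports call it
`T_c`) and `ΔT = T_e − T_o`.

## Statistics

CV is `100·SD/mean` with the sample (n−1) SD. Group comparison is one-way
ANOVA followed by **protected** Duncan's multiple range test: letters are
assigned only after a significant F test, otherwise all groups share one
letter. The protection matters — the unprotected test on three null groups
has an experimentwise error near `1 − (1 − α)² ≈ 0.10` at α = 0.05,
whereas the protected form measures ≈0.056 in a 1000-rep null simulation
(3 groups, n = 30), close to nominal. Duncan's least significant range for
a stretch of `p` ordered means uses the studentized-range quantile at the
protection level `(1 − α)^{p−1}` with the harmonic mean group size for
unbalanced designs; letters come from the standard ascending-means sweep
with maximal non-significant runs. Normality is gated per group by
Shapiro–Wilk at α = 0.05 (the routing helper `choose_test`), falling back
to tie-corrected Kruskal–Wallis. Pearson correlations use
pairwise-complete observations and a two-sided t test; no multiplicity
correction is applied across correlation matrices.

## Synthetic ground truth: what it emulates, and what it does not

- **Self-affine surfaces** are synthesized spectrally: white Gaussian
  noise shaped by the radial amplitude `|k|^−(H+1)` (power `|k|^−2(H+1)`),
  Hermitian symmetry inherited from the real input noise, no window at
  generation, normalized to zero mean and unit variance. Expected
  recovery: `|D̂ − (3 − H)| ≤ 0.1` at 512², averaged over ≥ 5 seeds, for
  `H ∈ {0.3, 0.5, 0.7}`.
- **Anisotropic Gaussian fields** convolve white noise with an
  axis-aligned Gaussian of standard deviations (ℓ_row, ℓ_col) under
  periodic boundary conditions, giving the separable autocorrelation
  `exp(−Δy²/4ℓ_row² − Δx²/4ℓ_col²)` and the exact ratio
  `Str_true = min ℓ / max ℓ`; recovery within ±0.1 at 512².
- **Granule packings** place non-overlapping discs (≥ 2 px gaps, so no
  segmentation merge is possible) with areas drawn uniformly inside each
  type band with ~1 px-of-radius margins; each rasterized disc's pixel
  area is re-checked against the classifier and redrawn if discretization
  flipped the label, making the returned per-type counts exact by
  construction. The default request (2 A, 10 B, 50 C at 0.2 µm/px on
  512²) realizes a solid fraction near 0.12; the spec's target fraction is
  a consistency report (a warning beyond ±0.05), not a packing driver.
- **Kernel silhouettes** are filled ellipses with sub-pixel centers;
  ground truth is the analytic area `πLW/4` and Ramanujan's first
  perimeter approximation (relative error < 5·10⁻⁵ up to 4:1 aspect).
- **PSD mixtures** are exact binned CDFs of lognormal mixtures on
  log-spaced bins spanning ±4 geometric SDs, with percentiles from the
  analytic mixture CDF by root finding; the histogram carries no sampling
  noise.

Every generator is a pure function of its spec, seed included.

These surrogates validate the *measurement chain*, not SEM physics: they
contain no charging artifacts, depth shading, protein-vs-starch contrast
variation, overlapping or non-circular granules, or detector noise.
Passing recovery tests therefore demonstrates correctness of the
estimators under their stated models, not that a particular micrograph's
binarization or pixel scale is right — those remain the analyst's inputs.
Reference microstructure values measured on original instrument images
(solid shares, χ, Str, D, τ_c of specific cultivars) depend on unpublished
pixel scales and so serve as plausibility ranges only; the bundled
cultivar tables are used for the arithmetic worked examples (shape
descriptors, SPAN, ΔT, energy reductions, correlations on cultivar means),
which do reproduce exactly or to the rounding of their printed inputs.

## Problem sizes and determinism

Recovery checks run at 512² fields with 5 seeds per condition, 20 random
packings, 200 random images for the Minkowski oracle and 1000 null
replicates for the Duncan calibration — sizes at which the statistical
tolerances above are comfortably met while the whole suite stays fast.
All randomness flows through explicit integer seeds (`numpy`'s
`default_rng`); no global state is used, and identical specs produce
bit-identical artifacts, which the CLI manifest verifies by checksum.

## Known limitations

- The watershed can oversplit strongly non-convex granules fused in long
  chains; `min_distance_px` trades merge risk against split risk and
  should be set near the smallest expected granule radius.
- `S` (boundary share) is resolution-dependent on real micrographs —
  boundary pair counts grow with magnification for rough interfaces; only
  compare values at matched pixel scales.
- The fractal fit assumes a single scaling regime below the corner; use
  the monofractality flag before trusting `D` on unfamiliar material.
- PSD percentile accuracy is limited by bin resolution near steep CDF
  segments (≈2 % at 100–150 log-spaced bins).
- Duncan letters are display groupings, not adjusted p-values; the
  protected variant controls the experimentwise rate only under the
  global null.
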