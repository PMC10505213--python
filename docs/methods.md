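# Methods

This note documents the models, estimators and numerical choices behind
`doct`, what the synthetic phantom does and does not emulate, and the known
limitations of the approach.

## Scan protocol and timing model

The repeated raster protocol splits the lateral field into `n_regions`
regions of `locations_per_region` B-scan locations. One raster pass over a
region takes one frame repetition time Δt, so each location is revisited
every Δt and observed N = `n_repeats` times. Derived quantities
(`protocol_timing`) are exact arithmetic on these parameters:

- volume acquisition time = `n_regions · N · Δt` (inter-region flyback is
  not modeled; the default 8 × 32 × 204.8 ms = 52.4288 s),
- observation window = `(N − 1) · Δt` = 6.3488 s by default,
- Nyquist frequency = `1/(2Δt)` = 2.4414 Hz by default: dynamics faster
  than this alias in the sampled autocorrelation,
- frames per volume = `n_regions · locations_per_region · N` = 4096.

Values are stored at full precision and formatted to 4 significant digits
for display. `HIGH_DENSITY_PROTOCOL` (1 location, N = 350, Δt = 12.8 ms,
4.48 s total) provides the fine delay grid needed by the early decay
metric. Frame timestamps are assigned at frame granularity; per-pixel
timing jitter within a frame is ignored. Default voxel sizes spread a
1 × 1 × 2.91 mm³ field over a 512 (x) × 128 (y) × 1024 (z) grid; they are
plain parameters and phantoms override them.

## dB scaling

Dynamics metrics operate on dB-scaled intensity, `10·log10(max(I, floor))`.
The floor keeps logs finite at zero-intensity voxels; it defaults to 1e-7
of the volume's full scale (its maximum) and is configurable. Negative
intensities are rejected; converting an already-dB volume is a no-op with a
warning.

## LIV

LIV is the temporal variance of the dB sequence with divisor N (population
variance), so for i.i.d. Gaussian dB noise of standard deviation σ its
expectation is σ²(N − 1)/N — the calibration the test suite and acceptance
script verify by simulation (σ = 3 dB, N = 32 gives 8.71875 dB²). LIV is
non-negative and invariant under multiplication of the linear intensity by
a positive constant (an additive dB shift).

## Autocorrelation and OCDS

The autocorrelation at lag i is estimated as the Pearson correlation
between the two overlapping subsequences offset by i frames, each using its
*own* mean and variance ("local Pearson"). This choice is tolerant of the
short N = 32 series, guarantees ρ(0) = 1 and |ρ| ≤ 1, and makes the curve
invariant under any affine transform a·I_dB + b (a > 0). A normalization by
the product of the two variances (rather than its square root) would not be
a correlation — curves would not start at 1 — so the Pearson form is used.
Zero-variance subsequences (constant background) make the lag invalid; such
voxels get LIV = 0 and OCDS = 0 with an explicit invalid flag rather than
NaNs.

OCDS is the negated OLS slope of ρ(τ) over the grid delays inside a window,
inclusive at both ends (grid matching tolerance 1e-9 ms): positive for
decaying correlation, negative (retained, not clipped) for a rising curve.
Windows must cover at least two grid delays; the late window
[204.8, 1228.8] ms covers lags 1–6 of the standard grid, the early window
[12.8, 64] ms lags 1–5 of the high-density grid. No spatial averaging or
curve smoothing is applied before the fit.

### Estimator behavior at small N

Two properties of the per-pixel estimator at N = 32 matter when
interpreting OCDS_l:

- The local-Pearson ACF of white noise has a small systematic negative
  bias of order 1/N (≈ −0.03 per lag). The bias is nearly constant across
  the fitted lags, so the fitted *slope* — and hence OCDS — remains
  unbiased around 0 for white noise.
- Because correlation is amplitude-invariant, a nearly frozen speckle field
  (τ_c far beyond the observation window) still shows apparent decay from
  the *shape* of its smooth trajectory once segment means are removed. As a
  result the measured mean OCDS_l rises monotonically from ≈ 0 for
  sub-frame-interval dynamics (τ_c ≲ 50 ms, aliased to a flat late ACF)
  through ~1e-4 ms⁻¹ at τ_c = 200 ms to a plateau of ~5–6 × 10⁻⁴ ms⁻¹ for
  τ_c ≳ 5 s, rather than decaying again in the frozen limit. OCDS_l should
  therefore be read as "slow-dynamics presence" relative to the window, not
  as an invertible decorrelation-rate estimate; the property tests assert
  the monotone rise over 50 → 200 → 1000 ms where the ordering is
  unambiguous.

## Pseudo-color rendering

Images are composed in HSV space: hue = metric linearly mapped from
`metric_range` onto [0°, 120°] (red = low, green = high), value = mean dB
intensity linearly mapped from `intensity_range_db` onto [0, 1], saturation
fixed at 1 (not configurable). Default hue windows — LIV [0, 10] dB²,
OCDS_l [0, 6 × 10⁻⁴] ms⁻¹ — and the default value window
[volume minimum + 5 dB, 99.9th percentile] were calibrated on the phantom
scenarios; they are display parameters only and affect no quantification.
Slices are single-voxel planes (en face = constant z, B-scan = constant y).

## Segmentation and quantification

Voxels strictly above a configurable dB threshold are grouped by
6-connectivity (face neighbors). The well-plate bottom, which is also
bright, is removed by an automatic rule: a component is a plate if its
lateral footprint covers ≥ 80% of the field, its z extent is at most a slab
thickness (default 6 voxels), and it lies near the deepest z (within twice
the slab thickness of the bottom). A manual z-exclusion range is available
as the faithful alternative to hand removal; both modes are recorded in the
mask's provenance, along with threshold and connectivity, for
reproducibility. The spheroid is the largest remaining component.

Quantification over the mask: volume = voxel count × voxel volume;
mean LIV and mean OCDS_l are arithmetic means; necrotic ratio = fraction of
masked voxels with metric strictly below the cutoff (3 dB² / 2 × 10⁻⁴
ms⁻¹ defaults), so a voxel exactly at a cutoff counts as viable.

## Group statistics

`compare_groups` is a two-sided Mann-Whitney U test. For group sizes up to
8 the p-value is exact: all C(n1+n2, n1) assignments of the pooled
mid-ranks are enumerated and arrangements whose U deviates from the null
mean n1·n2/2 at least as much as observed are counted (ties handled by
mid-ranks; for tie-free data this equals the doubled one-sided exact
p-value). Larger groups use the tie-corrected normal approximation. Note
the exact two-sided minimum for n = 5 vs 5 is 2/252 ≈ 0.0079.
`time_course_table` summarizes per-(condition, day) replicates with mean,
standard deviation (n − 1 divisor) and n, supports explicit outlier
exclusion (n is decremented and flagged), and reports consecutive-day
p-values per condition and metric.

## Synthetic phantom

The phantom emulates the *structure* of the measurement — concentric
dynamics domains with known geometry — so every pipeline stage can be
validated against ground truth. Per voxel, the complex speckle field is

    field(t) = √(1−f) · e^{iφ₀}  +  √(f/K) · Σ_{k=1..K} d_k(t)

with f the region's dynamic fraction, φ₀ a fixed random phase, and each
d_k an independent circular complex Gaussian Ornstein–Uhlenbeck process
with lag autocorrelation exp(−Δ/τ_c). The complex-Gaussian form (amplitude
and phase both evolving) is chosen over fixed-amplitude random-phase
phasors because its field autocorrelation is *exactly* exp(−Δ/τ_c), so the
region parameter τ_c maps directly onto the delay axis probed by OCDS;
K = 10 phasors per voxel keep the summed field in the fully developed
speckle regime (intensity exponentially distributed, coefficient of
variation 1, when f = 1). Intensity is |field|² scaled to the region's mean
backscatter level, plus additive clipped-Gaussian intensity noise at the
configurable noise floor (default −25 dB, σ = one fifth of the floor
level). Limits: f = 0 gives a constant sequence (LIV = 0); f = 1 with
τ_c ≪ Δt gives i.i.d. frames; τ_c far beyond the window gives frozen
speckle.

Geometry is a nested-ball spheroid (core ≤ rim, optional shell) over
background, with an optional full-footprint plate slab at the deepest z;
regions must tile the grid without overlap. Reproducibility: each region is
generated as one block from an independent `SeedSequence([seed, label])`
stream with voxels in fixed C order, and the noise field from its own
stream, so volumes are bit-identical for a fixed spec.

Scenario presets (`scenario_library`) encode qualitative patterns only:
`mcf7_control` (weak slow core / strong rim), `mcf7_taxol_1um` (low / high
/ low concentric decay-speed domains), `ht29_control` (strong *fast* core,
τ_c = 50 ms < Δt, so the core has high LIV but aliased, near-zero OCDS_l),
`ht29_sn38` (adds a thin fast peripheral shell), and `growth_series`
(core/rim radius ratio 0.4 → 0.6 → 0.8 over virtual treatment days 1, 3,
6). Scenario grids are 32 × 48 × 48 voxels at 0.02 mm isotropic with a
0.28 mm rim radius — large enough for stable region statistics, small
enough that a full pipeline run takes about a second.

What the phantom does *not* emulate: the OCT point-spread function and
speckle spatial correlation (voxels are independent), attenuation and
shadowing with depth, sample bulk motion, polarization effects, and any
quantitative mapping from real intracellular motility to (f, τ_c) — the
phantom parameters are synthetic labels, not biological magnitudes.
Passing tests therefore demonstrate that the estimators and the
segmentation/quantification chain recover constructed contrasts under
realistic speckle statistics, not that the pipeline reproduces any
particular biological measurement.

## Known limitations

- OCDS_l saturates rather than vanishes for very slow dynamics (see
  estimator behavior above); distinguishing "slow" from "static" requires
  the fluctuation magnitude (LIV) alongside.
- Dynamics faster than the 2.44 Hz Nyquist limit of the standard protocol
  are not quantifiable by OCDS_l (they alias to a flat late ACF); the
  high-density protocol and OCDS_e cover that regime at the cost of
  single-location coverage.
- Segmentation is a global threshold plus connectivity; spheroids touching
  the plate (face-connected components merge) need the manual z-exclusion
  mode.
- The exact Mann-Whitney enumeration is combinatorial; group sizes above 8
  switch to the asymptotic approximation.
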