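# Methods

## Hologram model and normalization

An inline hologram is the interference of the unscattered reference wave R
with the object wave O on a single camera plane, `I_H = |R + O|²`. For weak
scatterers (`|O| ≪ |R|`) the normalized contrast

    O(x,y,0) ≈ (I_H − |R|²) / (2|R|²)

recovers the real part of the object wave up to a term `|O|²/2`. The
background `|R|²` is a separate recording; pixels ≤ 0 (dead pixels) are
clamped to one camera count before the division, with a logged warning. The
contrast image is strictly zero-mean only in the weak-object regime; with the
generator's default bead amplitude (0.15 relative to the reference) the
residual mean is a few percent of the RMS, which is immaterial downstream
because detection thresholds are relative and parabolic masking is local.

## Back-propagation

Propagation over a distance z is evaluated spectrally with the
angular-spectrum transfer function `H(f; z) = exp(i z √(k² − 4π²|f|²))`,
`k = 2πn/λ`. This is the analytically exact Fourier transform of the
Rayleigh–Sommerfeld propagator for band-limited fields; the test suite pins
the equivalence against a direct O(N⁴) spatial-domain convolution with the
first RS kernel on 64×64 grids (relative deviation ~2×10⁻⁵ for a
band-limited source, interior region).

Conventions and numerical choices:

* The wavenumber is carried as a magnitude; propagation direction lives in
  the sign of z. z > 0 points from the hologram (focal) plane toward the
  sample. All lengths are nanometres internally.
* Evanescent components (`4π²|f|² > k²`) are zeroed for z ≠ 0 — at
  micron-scale propagation distances they only amplify noise. At z = 0 the
  kernel is the exact identity (including the evanescent band), so zero
  displacement returns the input bit-for-bit up to FFT round-trip error.
* Because the contrast image is real, its spectrum is Hermitian and the
  reconstructed intensity is symmetric in ±z; scanning positive z only is
  sufficient and sign ambiguity does not arise in practice.
* An optional Gaussian low-pass (sigma in cycles/nm, i.e. frequency space)
  can be applied to the spectrum before the inverse transform.
* No zero-padding by default (`pad_factor = 1`); wrap-around is mitigated
  downstream by the edge-margin exclusion of candidates. A pad factor > 1 is
  available for objects near the frame edge.
* `reconstruct_volume` refuses, with an explicit resource error, any volume
  above a configurable voxel budget (default 4×10⁸ voxels) rather than
  attempting the allocation.

## Localization

1. **In-plane candidates.** Maximum-intensity projection along z, then 2D
   peak finding (scikit-image) above a threshold that is a *fraction of the
   projection's global maximum* (default 0.3) — robust to exposure. A frame
   is declared empty unless the global maximum exceeds 10× the projection
   median; without this floor a noise-only frame would always yield
   "candidates". Candidates closer than `min_separation` (default: the
   column width, 15 px) keep only the brighter member (both flagged);
   candidates within `edge_margin` of the border are excluded with reason
   "edge". Exclusions are reported, never silently dropped.
2. **Coarse axial index.** A full-depth column (15×15 px) around each
   candidate is convolved (valid region, direct method) with the fixed 3×3×3
   Sobel-like kernel `[S1][0][−S1]`, `S1 = [[1,2,1],[2,4,2],[1,2,1]]`. For a
   focused point scatterer this derivative response is bipolar: a positive
   and a negative lobe roughly ±0.5 µm either side of the focus. When both
   lobes are present (negative extremum ≥ ¼ of the positive in magnitude)
   the coarse index is the rounded midpoint of the two extrema — the zero
   crossing, i.e. the intensity peak; a unipolar line falls back to its
   maximum, ties breaking to the lowest z. This keeps the coarse index
   within ~1 plane of truth instead of the lobe offset.
3. **Parabolic masking.** A 15×15×25-voxel intensity cuboid centered on the
   coarse position is refined iteratively: weight each voxel by
   `max(0, 1 − Σᵢ((uᵢ−cᵢ)/aᵢ)²)` (semi-axes aᵢ = cuboid half-extents,
   offsets u from the cuboid center, current estimate c), move c to the
   weighted centroid, stop when the shift < `mask_tolerance` (default 0.01
   voxel) or after `max_iterations` (default 100). The weights are evaluated
   at continuous offsets; the image is never interpolated. An exactly
   symmetric cuboid converges at its center in one iteration; the fixed
   point matches an independent dense-grid search to < 10⁻³ voxel.
   Refinement uses the *intensity* inside the cuboid (not the
   gradient-filtered volume), matching the role of the gradient as a coarse
   locator only; a gradient-weighted variant would be a one-line change.
   Cuboids clipped by the volume boundary are zero-padded and the resulting
   position flagged "clipped".
4. Physical coordinates are `(index + sub-voxel offset) × spacing`; z comes
   from the reconstruction grid plus the mask offset times the z step.

Determinism: the pipeline has no random state; identical inputs and
parameters give bitwise-identical outputs.

## Synthetic data

`forward_hologram` renders each bead as a point scatterer: a spherical wave
`a·(z₀/ρ)·e^{ikρ}` (amplitude normalized so the on-axis contrast equals the
bead amplitude, default 0.15) interfering with a unit reference wave;
`ρ` is regularized by half a pixel so an in-focus bead (z₀ = 0) renders as a
bounded bright spot. The camera is a pure gain mapping the brightest pixel
to the top of the count range (default 60 000, 16-bit scale), so
normalization recovers the physical contrast exactly; hologram frames carry
Poisson shot noise (seed mandatory), while the background is noise-free,
emulating the usual time-averaged background recording.

What the model omits — and hence what passing tests do *not* establish about
real data: Mie scattering structure of micron beads (ring contrast and
envelope differ from a point scatterer), camera read/fixed-pattern noise,
aberrations, illumination partial coherence, and the axial elongation bias
of real optics. The generator produces rings of the correct geometry, which
is what the localization algorithms consume; the method itself requires no
knowledge of particle size or refractive index.

`render_lut_pattern` / `compose_scene` implement the profile-revolution
protocol: a 1D radial profile (value at radius `(i+0.5)·bin_width` px) is
revolved about an arbitrary sub-pixel center, patterns are zero-centered so
overlaps sum, offset, affinely rescaled to the camera range (min→low,
max→high) and Poisson-sampled. In the paper-equivalent workflow the profiles
would come from an experimental bead z-stack; here they are extracted from
forward-model stacks, closing the generator/consumer round trip
(profile → image → profile agrees to < 1 % over the used radial range; the
innermost 2 bins average too few pixels and are excluded from matching).

Scenario builders: `crowding` (central bead + 0–8 crowders on a ring of
radius r_sep, one plane), `axial_crowding` (two beads, Δz and lateral offset),
`xy_steps` / `z_steps` (staircase protocols; defaults 19.5-nm lateral steps,
30-nm axial steps at 10-µm defocus).

## LUT baseline

The comparison method reduces a bead image to a radial profile (mean over
circles of radius `(i+0.5)·bin_width` around a sub-pixel center, bilinear
sampling) and matches it against a table built from a z-stack at 50-nm
defocus spacing. Matching is least squares over the radial range excluding
the innermost 2 bins; the minimizing row is refined by quadratic
interpolation of the score over the three bracketing rows (an exact row
match returns that row's defocus exactly; a minimum on the first/last row is
flagged "boundary"). In-plane centering finds the axis of mirror symmetry of
row/column sums: a coarse estimate from correlation with the reversed
profile, refined by minimizing the mirror error `Σ[p(c+u) − p(c−u)]²` on
successively finer grids (2×10⁻³ px on clean rings), iterated with window
re-centering. These choices are pinned by properties rather than by a
reference implementation: on isolated symmetric patterns the LUT and
holographic pipelines agree within a pixel in xy and within the row spacing
in z; with a crowding bead one bead diameter away the LUT's axial deviation
grows by orders of magnitude while the holographic pipeline's stays at the
tens-of-nanometres level — the documented failure mode that motivates
single-image holographic localization.

## Tweezer-track analysis

* **Linking** is greedy nearest-neighbor within a gate radius, assigning
  pairs in order of increasing 3D distance (exact ties to the lower bead
  id); unmatched detections start tracks, missed frames are explicit gaps.
* **Drift correction** subtracts the per-frame mean displacement of
  reference beads relative to their own first frame; frames without a
  reference get an interpolated correction and a warning. Idempotent after
  the first pass.
* **Axial correction** is user-parameterized: `linear` (slope/intercept from
  a bead-scan calibration — coefficients are data, not constants),
  `smallangle` (× n_medium/n_oil, default 1.33/1.515) or a monotonic
  `spline` knot table for nonlinear regimes; out-of-range values are
  extrapolated with a warning.
* **Dissociation**: the clock starts at magnet engagement (not recording
  start); the event time is the first of ≥ `absence_frames` (default 3)
  consecutive absent frames; beads present to the end are censored.
  Extension is measured against the pre-force baseline z. The
  single-tether gate requires reaching `gate_nm` (default 1000 nm ≈ 87 % of
  a 3.4-kbp tether's 1156-nm contour length at 0.34 nm/bp) within a
  response window (default 10 s) of force engagement — multivalent
  attachments extend shorter and respond in steps. Timestamps are carried
  per frame and never assumed uniform (MT schedules switch frame rates).
* **Survival** is fitted by least squares on the empirical fraction-
  remaining step curve, `S(t) = (1−c)e^{−k_off t} + c`, offset c fixed at 0
  unless requested; censored records count toward n (they remain attached),
  which is exactly what the offset term absorbs for long-lived
  subpopulations. Half-life `t_F = ln2/k_off`. Least squares on the decay
  curve is the field's convention for these plots; a maximum-likelihood fit
  on event times would be statistically preferable for small n and is a
  natural extension.
* **Bell model**: `ln t_F` is linear in F; the fit is ordinary least squares
  in log space, so a noise-free round trip is exact. `k_B = 0.0138065
  pN·nm/K`, default T = 298.15 K.
* **Force calibration**: `F = k_BT⟨z⟩/⟨δx²⟩` over a constant-magnet segment
  of ≥ 100 frames; a near-zero lateral variance is reported as a tracking
  failure, not an infinite force. Validated against an exact
  Ornstein–Uhlenbeck simulation of a tethered bead.
* **Step SNR**: step size divided by the mean within-dwell standard
  deviation; a noise-free staircase reports the sentinel `inf`.

## Problem sizes used in validation

Unit tests run on 64–256-px grids. The crowding study uses 512×512 grids
(100-nm pixels), eight crowders, r_sep ∈ {8, 16, 24} µm, bead-plane defocus
∈ {0, 10, 20, 30} µm, a ±3-µm z grid at 100-nm steps around each defocus,
and Poisson noise — 12 crowded scenes plus 4 baselines. The original
experiments used 1024×1024 grids; halving the field keeps all separations
inside the frame at identical pixel scale while keeping the full study
around a minute on one CPU. Measured at this scale, the central bead's
maximum deviation from its no-crowding baseline is ~0.04 µm axially and
~0.01 µm in plane — an order of magnitude inside the 0.6 µm / 0.04 µm bounds
reported for the original patterns, as expected for a cleaner forward model
with high-count shot noise only.

## Known limitations

* The point-scatterer forward model understates the pattern complexity of
  real 2.8-µm beads; absolute axial accuracy on real data depends on the
  user-supplied z-correction (the calibration coefficients are deliberately
  not hard-coded).
* The LUT baseline implements a least-squares profile match; published
  cross-correlation variants differ in windowing and normalization, so only
  order-of-magnitude failure behavior, not exact LUT error values, should be
  compared.
* A defocus of 0 (bead in the hologram plane) carries no ring information;
  the axial estimate there reflects the grid floor, and only *relative*
  deviations are meaningful — absolute z at near-zero defocus is not
  recoverable from an inline hologram.
* Greedy linking is adequate for MT bead densities; it is not a
  multi-hypothesis tracker and will mis-link crossing trajectories closer
  than the gate radius.
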