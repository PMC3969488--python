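# Methods

## The measurement problem

The size of micrometre-scale drug (API) particles inside a finished tablet
cannot be measured by the usual powder techniques (laser diffraction,
image analysis of the loose powder): once the API is compacted into an
excipient matrix, only a chemically selective imaging method can tell API
from matrix. Raman chemical imaging does this by acquiring a full Raman
spectrum at every pixel of a scanned tablet cross-section and exploiting a
Raman band that the API has and the excipients lack.

The pipeline implemented here:

1. **Second-derivative preprocessing.** Every pixel spectrum is replaced by
   its Savitzky–Golay second derivative (31-point window, cubic
   polynomial). Constant and linear baseline contributions vanish
   identically; broad fluorescence backgrounds are strongly suppressed. A
   genuine band becomes a negative trough, so the derivative is multiplied
   by −1 downstream to make particle pixels bright.
2. **Univariate band image.** The 2-D image of the sign-flipped derivative
   at a single component-specific channel (1,605 cm⁻¹ for polystyrene,
   1,601 cm⁻¹ for ebastine), choosing the nearest channel to the requested
   wavenumber (ties resolve to the lower wavenumber).
3. **mean + k·σ binarization.** The classification threshold is computed
   from the intensity histogram of the whole analysis area:
   t = mean + k·σ, with σ the population standard deviation over all
   pixels and k = 0.5 the validated default. Pixels with intensity **at or
   above** t are object.
4. **Particle sizing.** Connected object regions (8-connectivity by
   default) are particles; each is assigned the equivalent circular
   diameter d = 2·√(A/π) of its pixel area A. Per-area summaries (mean,
   sample STD, object-area %, count) are pooled across the several areas
   scanned per cross-section with particle-count weights — identical to
   summarizing the concatenation of all particles. The pooled STD uses the
   within + between variance decomposition, which is algebraically the
   sample STD of the concatenated diameters.
5. **Calibration.** Model tablets substitute certified polystyrene
   microsphere standards (4.9/9.8/15.8 µm) for the API. Recovery
   (100·post/pre) per standard and the OLS regression (with intercept) of
   post-formulation pooled means on pre-formulation means quantify how
   faithfully a threshold recovers known sizes; the validated k = 0.5 gives
   a slope of ≈1.02 across the three standards, while k = 0 over-sizes
   (slope 1.13) and k = 1.0/1.5 progressively erode particles
   (slopes 0.78/0.49).

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| SG window | 31 | channels | the method's stated filter width; heavy smoothing is intentional (noise rejection dominates band-shape fidelity here) |
| SG polynomial order | 3 | — | conventional for second derivatives; exposed as a knob |
| threshold multiplier k | 0.5 | — | the value validated against size standards; 0, 1.0, 1.5 retained for sweeps |
| connectivity | 8 | — | avoids splitting a single sphere at diagonal stair-steps; 4 available |
| σ estimator (histogram) | population (n) | — | deterministic choice; at 10⁴ pixels the n vs n−1 difference is ~10⁻⁴ relative |
| STD of diameters | sample (n−1) | µm | conventional estimator for the small per-area particle counts |
| edge margin | window//2 = 15 | channels | SG output at the axis ends is untrusted; band selection there is refused rather than silently degraded |

Derivative values are scaled by the channel spacing (per cm⁻²), so
thresholds are comparable across maps with different axes.

Edge-touching particles are included in all statistics but flagged, letting
callers exclude them; no minimum-size filter is applied (sub-resolution
noise control is the threshold's job).

## The synthetic phantom

Because no instrument data are deposited, the `phantom` module generates
the model-tablet experiment in silico: a 100 × 100 px section at 1 µm/px
over 200–3,700 cm⁻¹ at 2 cm⁻¹ spacing (a 1,400–1,800 cm⁻¹ "thin axis"
option exists for fast tests), with

* **disk placement** — diameters ~ Normal(mean, SD) truncated at 1 µm,
  certified values per preset (ps5: 4.9 ± 0.5, ps10: 9.8 ± 1.0,
  ps15: 15.8 ± 1.3 µm; ebastine: 4.11 ± 3.78 µm); centers by rejection
  sampling until the target area fraction is reached, non-overlapping with
  one pixel of clearance, except that with probability 0.05 a disk is
  placed tangent to an existing one and tagged with a shared agglomerate
  id. Disks lie fully inside the image (the truth channel stays
  unambiguous). A bounded attempt budget turns unreachable fractions into
  an error.
* **spherical response profile** — the per-pixel particle signal is the 4×
  supersampled mean of √(1 − (ρ/r)²), the relative chord thickness of a
  sphere sectioned at its equator: the Raman response scales with the
  particle material in the focal volume, peaking at the centre and falling
  toward the rim. This is what makes the estimated size threshold-dependent
  in the characteristic way the method shows on real tablets (a low
  threshold over-sizes, a high one strongly under-sizes large spheres).
  The geometric (flat) disk coverage is retained as the ground-truth
  fraction map, and a `spherical_response=False` switch restores a flat
  profile. A one-pixel linear "halo" skirt (peak relative intensity 0.15)
  outside each disk mimics surface-roughness/penetration blur
  qualitatively.
* **spectral model** — each pixel's spectrum is
  f·S_particle + (1 − f)·S_excipient + linear baseline drift + N(0, σ_noise).
  Excipient identity is categorical per pixel (granule-scale patches:
  lactose-like 60 %, cellulose-like 8 %, matrix 32 %). The lactose analog
  carries a modest 1,620 cm⁻¹ band (spectral crowding next to the analysis
  band); the cellulose analog's 1,633 cm⁻¹ band sits on the most negative
  side lobe of the smoothed second derivative of a 1,605 cm⁻¹ band
  (measured response −0.64 of peak), giving a minority of background pixels
  distinctly negative flipped-derivative values. This reproduces the
  bimodal histogram structure the method relies on: a tight background mode
  with a negative tail, and a separated positive particle mode.
* **defaults** — target area fraction 0.12 (≈ the 6.25 wt% formulation
  loading at polystyrene vs excipient densities, and consistent with the
  ~14 % object area observed at the validated threshold);
  noise σ 8 counts on a 1,000-count particle band (high-SNR acquisition,
  matching the clean histogram separation the method's source data show);
  baseline drift amplitude 60 counts. All randomness flows from a single
  seed through one generator in fixed call order, so regeneration is
  bitwise identical.

**What the phantom does not emulate:** real Raman band shapes and widths,
confocal depth response, cosmic rays/detector artifacts, random-latitude
sphere sectioning (disk diameter = sphere diameter here), partial particles
at the field edge, and instrument wavenumber calibration drift. Passing
phantom tests therefore demonstrates the correctness and internal
consistency of the algorithm chain under realistic signal structure — not
instrument-level validation.

Measured behaviour at defaults (recomputed by `scripts/acceptance.py` and
the test suite, never hard-coded): pipeline pooled means at k = 0.5 recover
phantom truth means to within a few percent for all three standards, the
pipeline-vs-truth regression slope is ≈0.96–0.98, object area % is
non-increasing in k, and ten-fold noise inflation measurably degrades
recovery.

## Numerical choices and degenerate inputs

* Nearest-channel ties resolve to the lower wavenumber (documented,
  arbitrary).
* Binarization uses ≥, so a pixel exactly at threshold is object.
* Histogram σ = 0 (constant image) makes the threshold the mean — every
  pixel is then object, which is the correct limit of the ≥ rule.
* An empty particle set summarizes to count 0 with NaN mean/STD; pooling
  over all-empty areas is an error.
* A single analysis area pools to itself; a single standard in a sweep
  yields a flagged NaN slope rather than an error.
* Axis uniformity is enforced to 10⁻⁶ relative before SG filtering;
  descending on-disk axes are normalised to ascending on read.
* CSV readers use round-trip float parsing so written tables reproduce
  diameters bit-exactly.
* Maps carry a sign-convention flag; differentiating an already
  differentiated map is refused.

## Known limitations

* Agglomerates and colocalized particles are sized as single objects — a
  property of the method itself, reflected (not corrected) here.
* The mean + k·σ rule assumes the particle phase is a minority of pixels
  with a separated intensity mode; formulations whose API is finely
  dispersed (no distinct histogram mode) are outside its validity, as are
  particle loadings approaching the background mode in pixel share.
* Pre-formulation references are user-supplied constants; the default
  semantics compare against a measured pre-formulation Raman mean, not
  certified values, because both sides then share the method's bias.
* The regression is fit to the per-standard pooled means (one point per
  standard); per-area fitting is available but not the default, as pooled
  fitting is what reproduces the published slopes to printed precision.
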