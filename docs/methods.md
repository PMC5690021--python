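# Methods

## Problem and model

After manual patient positioning on orthogonal (frontal/lateral) X-ray
images, the residual setup error is the rigid translation that best maps
the planning reference projection (DRR) onto the in-room radiograph (DR),
expressed on the couch axes. Rotations are out of scope: the measurement
happens after positioning is complete, when residual rotation is
negligible, and roll is in any case unobservable from two orthogonal
projections without 2D–3D registration.

The similarity is a weighted zero-mean normalized cross-correlation. For a
candidate offset **d** of the DRR, both images are multiplied by an
isocenter-centered Gaussian ω(**p**+**d**) = exp(−|**p**ic−**p**−**d**|²/2σ²)
evaluated at the displaced position — the weight field travels with the
candidate so that importance always concentrates on anatomy near the
planned isocenter, where dose-relevant alignment matters most and where
collimation never intrudes. Means are taken over the valid (unmasked,
in-bounds) window pixels of the weighted values, per candidate. The
denominator is the standard ZNCC form √(ΣΣ); this is the only reading
consistent with a zero-mean normalized correlation bounded in [−1, 1].

## Parameters

| parameter | default | meaning |
|---|---|---|
| `s` | 480 px | captured-image side length |
| `sn` | 0.8 | window fraction; N = round(s·sn) = 384 px |
| `s_sigma` | 0.4 | weight width; σ = N·s_sigma = 153.6 px |
| `M` | 40 px | search-window side; integer offsets span [−20, 19] |
| `mt` | 30000 | Sobel threshold for field-edge masking, 16-bit scale |
| `subpixel_step_px` | 0.05 | refinement grid pitch (≈ 0.022 mm) |
| `pixel_spacing_mm` | 0.446 | captured-image spacing |
| `min_valid_px` | 16 | minimum usable pixels per candidate |

Intensities are normalised to a 16-bit scale on load (8-bit inputs are
multiplied by 257) so that `mt = 30000` keeps a single meaning.

## Search and numerical choices

- Integer offsets span the centered grid Δ ∈ [−⌊M/2⌋, ⌈M/2⌉−1] per axis.
  The refinement re-evaluates R on a fractional grid of pitch 0.05 px
  within ±1 px of the integer peak, sampling the DRR bilinearly; the grid
  contains the integer peak, so refinement never lowers R. 0.05 px is an
  order of magnitude below the accuracy the method is expected to deliver,
  at bounded cost.
- Ties at the argmax break toward the smallest Euclidean offset, then
  row-major scan order — fully deterministic; the matcher uses no random
  numbers anywhere.
- Candidates with fewer than `min_valid_px` usable pixels, or zero
  variance in either weighted patch, are undefined (NaN) and skipped;
  masked pixels are excluded from all sums rather than zero-filled so the
  collimated region cannot bias the means. A run where every candidate is
  undefined raises a distinct matching error.
- A correlation peak on the search-grid border is reported with a warning
  flag: the true displacement likely exceeds the search range.
- Images smaller than 3×3, windows that do not fit the image, and overlay
  masks covering the whole frame are rejected with explicit errors.

## Preprocessing

Annotation pixels are detected by per-channel color match against a
configurable palette (the generator's palette by default) — the rendering
internals of a clinical capture system are not modelled, and color
matching makes the step testable end to end. Inpainting is an iterated
8-neighborhood mean ("onion peel"): each pass fills every annotation pixel
with at least one valid neighbor, repeating with the updated image until
none remain; it is deterministic, strictly local, and leaves non-annotation
pixels bit-exact.

Collimator masking thresholds the Sobel gradient magnitude (two 3×3
kernels combined in quadrature, borders edge-replicated) at `mt` and scans
each row from both ends and each column from both ends; pixels up to and
including the first supra-threshold point are blocked, and the final mask
is the union of the row-wise and column-wise sets. Rows or columns with no
qualifying point contribute nothing: the collimated region always
terminates in a high-contrast field edge, so an edge-free line is treated
as usable. Two consequences are documented rather than "fixed": corner
rectangles of a fully collimated border are unreachable by either scan
(their rows and columns are entirely dark) — harmless, since the matching
window is central — and monotonicity of the blocked set in `mt` holds only
while each line retains a qualifying edge.

## Couch-space conversion

Frontal x ↔ lateral couch axis, lateral x ↔ vertical axis, both y ↔
longitudinal axis. The reported displacement sign is "DRR position minus
DR position", so a couch correction equals the negated report; in the
generator a positive couch movement produces a positive image-content
displacement of equal magnitude along the mapped axis. Per-position errors
are computed against the registration at the origin couch position; the
longitudinal error averages the two views' y terms. Aggregates use
population standard deviations (divisor n), the convention under which the
published table's Total row reproduces from its rows. Full precision is
kept internally; 2-decimal rounding is display-only.

## Synthetic phantom

The generator emulates the accuracy experiment's inputs, not X-ray
physics: soft-edged ellipses/bars (pelvic brim, femoral heads, sacrum-like
bar) over a graded background plus band-limited texture give the
correlation surface a sharp peak; the lateral view is rendered at 0.55×
structure contrast, mirroring the longer lateral transmission path. The DR
is the DRR bilinearly translated by the view-mapped couch shift, passed
through a gain/offset drift (0.92, +1500), additive Gaussian sensor noise,
sharp-edged collimation bands, and palette-colored annotations. All
randomness derives from one integer seed; outputs are bit-reproducible.

Noise level (SD 800 counts, ≈ 5% of bone contrast) was chosen once on
physical grounds. With a 384 px correlation window, zero-mean sensor noise
averages over ~1.5·10⁵ pixels, so it perturbs the peak by far less than
the published 0.23 mm phantom accuracy — that figure is dominated by
effects a rigid synthetic phantom does not have (anatomy change, capture
variability, preprocessing failures on clinical screens). Passing the
synthetic experiment therefore demonstrates the correctness and subpixel
behavior of the chain, not clinical-grade accuracy on real captures.

One geometric fact is inherited faithfully rather than hidden: at
0.446 mm/px the ±10 mm pattern positions are 22.4 px, outside the centered
M = 40 search range (−20…19 px), so those registrations clip at the search
border (~0.6–1.1 mm error, border-flagged) while interior positions
recover to ~0.02 mm. The ten-position mean RMSE lands near 0.19 mm, inside
the published 0.23 mm.

## Problem sizes used

The accuracy experiment (tests and `scripts/acceptance.py`) runs at the
full default scale: 480 px images, N = 384, M = 40, eleven positions × two
views (~2–3 minutes on one CPU). Unit and property tests use 40–192 px
configurations of the same code paths; the brute-force oracles (literal
loop transcriptions of the correlation, the exhaustive fractional-grid
search, and the error equations) run on ≤ 64 px inputs.

## Known limitations

- Translations only; no rotation/scale, no multi-resolution pyramid.
- The collimator scan assumes an axis-aligned rectangular field edge
  stronger than `mt`; failure of that extraction was the method's main
  clinical failure mode and is reproduced, not mitigated.
- The phantom is procedural: no scatter, beam hardening, deformable
  anatomy or gas pockets; correlation of the matcher with simulated
  "pointing" observers (SD 0.21 mm) stands in for human measurements.
- The ±10 mm search-range clipping above applies whenever
  |shift| > M/2 · spacing; widen `M` for larger capture ranges.
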