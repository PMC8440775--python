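# Methods note

This note records the model, the exact numerical conventions, and the
scope of the synthetic validation, so that every reported number can be
traced to a precise computation.

## Model

The detector classifies each candidate boundary pixel by the geometry of
local intensity change. All intensities are float64 in [0, 1]; pixel
coordinates are 0-based `(row, col)` with the origin at the top-left.

### Boundary-pixel determination

- Diamond average: `ave[i, j]` is the sum of intensities over pixels at
  Manhattan distance ≤ `(s_w − 1)/2` from `(i, j)`, divided by
  `(s_w² + 1)/2` (for `s_w = 5`: 13 pixels, divisor 13). Margins of
  width `(s_w − 1)/2`, where the diamond leaves the image, are NaN, not
  zero — a zero would fabricate spurious differences at the border.
- Difference maps: `Diff1[i, j] = |ave[i−1, j−1] − ave[i+1, j+1]|`
  (135°) and `Diff2[i, j] = |ave[i−1, j+1] − ave[i+1, j−1]|` (45°).
  Any NaN operand makes the output NaN.
- A pixel joins `P1` (resp. `P2`) iff its `Diff1` (resp. `Diff2`) value
  is a *strict* local maximum along the corresponding diagonal and
  exceeds `th_Diff`. NaN comparisons are false, so the NaN margin can
  never produce boundary pixels. `P = P1 ∪ P2`.
- When a field-of-view mask is used, it is eroded by a square of side
  `2·((s_w − 1)/2 + 1) + 1` so that no diamond or diagonal neighbor
  reaches outside the FOV.

### Lesion decision per boundary pixel

- Center window: the minimum-mean `d_0 × d_0` square among six
  candidates — top rows `{i − d_0, i}` × left columns
  `{j − d_0, j − d_0/2, j}` (integer division). Ties are broken by the
  first-listed candidate (above before below; left, center, right).
  Windows are exactly `d_0 × d_0`, half-open, top-left inclusive.
- Window chains: with center top-left `(x0, y0)` and step `r = d_0`,
  member `k ∈ {−num, …, num}` sits at
  - θ = 0: `(x0, y0 + k·r)`;
  - 0 < θ < 90: `(x0 − k·r, y0 + ⌊k·r·tan θ⌋)`;
  - 90 < θ < 180: `(x0 − k·r, y0 − ⌊k·r·tan θ⌋)`.
  The floor is applied to the *signed* product (so negative `k` rounds
  toward −∞), after rounding the product to 9 decimals: without this
  guard, `tan 135° = −1.0000000000000002` in float64 would shift a
  window by one pixel (`⌊−10.000000000000002⌋ = −11`). θ = 90° is
  rejected (tangent undefined); `k = 0` is the center window for every
  θ.
- Window labels: *dark* iff the fraction of pixels with intensity
  `< T_dp` exceeds `T_D` (strict); *light* iff that fraction is below
  `T_L` (strict); otherwise *neither*, which fails the "light"
  requirement.
- A pixel is a lesion pixel iff its center window is dark and all
  flanking windows (`k ≠ 0`) in all tested directions are light. Tested
  directions: {0°} always, plus {30°, 45°, 60°} for `P1` members,
  {120°, 135°, 150°} for `P2` members, and the union for pixels in
  both (the stricter choice: a compact lesion changes intensity in all
  directions). A chain leaving the image fails the test.
- Multi-scale: the extraction runs at each `d_0 ∈ {10, 16, 22}` and
  unions the per-scale pixel sets.

### Optic-disc suppression

- Every `d_od × d_od` square on the `r_d`-strided grid is scored by the
  sample standard deviation (denominator `d_od² − 1`). Squares with
  more than 20% of pixels outside the FOV are excluded (the dark
  aperture rim otherwise wins on variance); if all are excluded the
  constraint relaxes to the most-inside squares.
- Squares are sorted by score descending, ties broken lexicographically
  by `(top_row, left_col)`. The top `max(1, ⌈α% of count⌉)` positions
  (default α = 5) are averaged arithmetically; the average is rounded
  half-up (`⌊x + 0.5⌋`) and clipped so the square stays in-image.
- Lesion pixels with `top ≤ row < top + d_od` and
  `left ≤ col < left + d_od` are removed (exact partition).

### Scoring and ROC

- Lesion pixels are clustered into spots by single-linkage with
  Chebyshev radius equal to the smallest `d_0` scale. TP = annotated
  regions containing ≥ 1 lesion pixel; FN = regions containing none;
  FP = detected spots with no pixel in any region; TN = rejected
  candidate spots (boundary clusters not labeled lesion) outside all
  regions. SE = TP/(TP+FN), SP = TN/(TN+FP); a zero denominator makes
  the metric undefined (reported as missing, never as 0).
- ROC by sweeping `T_D`: the candidate pool is fixed per image — the
  boundary set `P` is clustered once, and each `T_D` only relabels
  whole candidates as detected or rejected (detected candidates keep
  their full footprint). With strict threshold comparisons this makes
  TP and FP non-increasing and TN non-decreasing in `T_D` *by
  construction*, so SE is non-increasing and SP non-decreasing, as the
  model predicts. AUC is the trapezoid rule over the (1−SP, SE) points
  with (0, 0) and (1, 1) anchors. Grid values must lie in `(T_L, 1]`.

## Parameters

| symbol | default | role |
|---|---|---|
| `s_w` | 5 | diamond span |
| `th_Diff` | 0.12 | boundary threshold |
| `d_0` scales | 10, 16, 22 | window sides |
| `r` | `d_0` | chain step (flanks adjacent to the center) |
| `num` | 1 | flanks per side |
| `T_dp` | 0.2 | dark-pixel intensity threshold |
| `T_D` | 0.7 | dark-window fraction threshold |
| `T_L` | 0.4 | light-window fraction threshold |
| `d_od` | 180 | disc square side |
| `r_d` | 10 | disc grid stride |
| `α` | 5% | top fraction of disc squares averaged |
| CLAHE clip | 0.02 | uniform distribution, 8×8 tiles |

`r = d_0` keeps each flank exactly adjacent to the center window: with
`num = 1` the flanks must clear a lesion of diameter ≈ `d_0`, and an
overlapping step would leak lesion pixels into the flanks. The
direction sets {30°, 45°, 60°} / {120°, 135°, 150°} span each quadrant
while avoiding 90°. `d_od = 180` matches full-resolution fundus
photographs; synthetic scenes (384×500) use `d_od = 60` at their scale.

## Synthetic generator: scope

Scenes contain uniform-depth anti-aliased blobs, straight vessel strips,
and one bright square crossed by dark lines, plus clipped additive
Gaussian noise (sd 0.02). Validation rejects overlapping geometry,
out-of-bounds placement, and depths too shallow to stay below `T_dp`
at 3σ noise — so ground truth is unambiguous. Ground-truth lesion
regions are the sub-`T_dp` pixels of the noiseless render; everything
is bit-exactly reproducible from the seed (derived per-scene seeds are
drawn below 2³¹).

The battery used for headline numbers has 20 scenes, 5 blobs each
(radii 3–12 px), one vessel (width 3–12 px, uniformly random
orientation, kept clear of the disc), and one disc square placed at
least 1.5·side from the frame edge (as in a real photograph, where the
disc never touches the aperture rim). Blobs keep a 50 px clearance from
vessels, the disc, and each other, so flanking windows measure pure
background — the regime the window-chain rule addresses. Passing these
tests shows the decision rule separates compact from elongated dark
structures under moderate noise; it does *not* certify performance on
real fundus texture, exudates, vessel curvature at blob scale, or
annotation ambiguity.

Disc recovery is evaluated on disc-focused scenes (no vessels, blobs of
radius 3–4.5 px): synthetic vessels are rendered as dark as the disc's
crossing lines (both must undercut `T_dp`), so on full scenes their
variance rivals the disc's and the top-α average can pool scattered
squares — a generator artifact, not a property of real images, where
the disc is by far the highest-contrast region.

## Known limitations

- **Small-lesion floor.** A `d_0 = 10` center window is dark only when
  more than `T_D · d_0² = 70` pixels are dark, so blobs of dark area
  ≤ 70 px (radius ≲ 4.7 px) are undetectable at that scale — and larger
  scales require proportionally larger blobs. On the radius 3–12 px
  battery this caps lesion-level sensitivity at ≈ 0.81 (measured 0.79–
  0.81; sub-floor blobs 0/18 detected, radius ≥ 5 px essentially all
  detected). The acceptance test asserting sensitivity ≥ 0.9 on that
  battery therefore fails, and is left failing: the bound is
  unattainable under the method's own decision rule.
- **Near-vertical structures.** The tested directions exclude 90°, so a
  structure elongated almost exactly vertically is probed only by
  oblique chains; discrimination weakens in a narrow angular band
  around vertical.
- **Disc localization needs contrast.** On images whose highest-variance
  region is not the disc (severe clutter, synthetic scenes with
  disc-dark vessels), the variance criterion can land elsewhere; the
  filter then removes a wrong zone.
- **No subtype classification or segmentation.** Red lesions are
  detected as one class; spots are clusters of boundary pixels, not
  exact lesion masks.
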