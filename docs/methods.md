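# Methods

## Model

`mirlight` treats lightness perception as probabilistic scene
decomposition: given a small calibrated luminance image *x* (cd/m²), infer
per-pixel illuminance *e* (lux) and reflectance *r* (proportion) under the
Lambertian relation *x = r·e/π*. Reflectance is fully determined by the
illuminance labeling, so the model is a conditional random field over a
discrete illuminance variable per pixel.

### Illuminance grid

81 log-spaced levels on [1, 10⁴] lux (step Δln e ≈ 0.115, i.e. ~12 % per
level). The grid must be fine enough to express the roughly one-step
illuminance separation that carries White's effect (reflectance ratio
0.46/0.41 ≈ e^0.115); 32 levels over the same range are too coarse. The
range covers dim interior to bright daylight illuminance.

### Unary potential

For pixel luminance *x* at level *e*, with *r = πx/e*:

* α·ln(e/e₁), α = 0.1 — lower illuminances are more likely. A weak,
  unbounded preference for darker interpretations.
* β·max(0, ln(r_max/r)), β = 0.3 (`anchor_weight`) — the anchoring pull:
  interpretations in which a surface sits far below the white point are
  increasingly unlikely. Together with the glow ramp this gives every pixel
  a *bounded* pull toward the illuminance at which it would appear white,
  which is what makes the highest-luminance anchoring tendency emerge: a
  uniform image is always labeled at the lowest level whose implied
  reflectance stays ≤ r_max.
* glow ramp γ·(r − r_max) for r > r_max = 0.9, γ = 100 — luminances above
  the white anchor read as self-luminous; the ramp is soft so small
  excursions (glow) remain representable.
* a flat cost of 10⁴ for r < r_min = 0.03 — implausibly black surfaces.
* zero-luminance pixels get a flat table (any illuminance is consistent
  with r = 0) and report reflectance 0.

### Pairwise potential

Adjacent pixels *i, j* pay *w_ij·(ln e_i − ln e_j)²*. The quadratic step
cost is deliberate: illumination changes are gradual, so the marginal cost
of deepening an illuminance step grows with its size. This produces stable
*interior* optima — moderate illusion magnitudes — rather than the
all-or-nothing behaviour of a linear cost, under which a region either
stays put or slides to its glow floor. The exponent is configurable
(`pairwise_power`).

The weight *w_ij* encodes what the luminance edge looks like:

| pair class | weight | reading |
|---|---|---|
| equiluminant (|Δx| ≤ 10⁻⁹) | w₀ = 600 | illumination almost never changes between identical luminances |
| X-junction colinear, sign-invariant | w_Xinv = 0 | transparency/shadow cue: illuminance edges are free |
| X-junction colinear, sign-variant | w_Xvar = 50 | reflectance-pattern cue (checkerboards): illuminance edges unlikely |
| plain luminance edge | w₁ = w_Xvar·exp(−MC_average) | adaptive, see below |

A 2×2 block qualifies as an X-junction iff all four within-block adjacent
pairs differ (two luminance edges genuinely cross); its vertical colinear
pair is sign-invariant iff the two horizontal luminance steps share a sign,
and likewise for the horizontal pair. A pair belonging to several blocks
takes the cheapest applicable class (invariant beats variant beats plain).

MC_total is the sum of Michelson contrasts |x₁−x₂|/(x₁+x₂) over all
adjacent pairs, and MC_average = MC_total/√(m²+n²) normalizes by the image
diagonal, making the statistic stable under pixel-replication upsampling.
w₁ equals 50 for a zero-contrast image and decays with articulation and
contrast — high-contrast scenes are expected to contain more illumination
change. The **original-model regime** instead fixes w₁ = 20 and gives
*every* X-junction colinear pair weight 0 regardless of polarity.

### Straightness

Every 2×2 block whose illuminance-edge pattern forms a corner (two edges
sharing a pixel, or three edges) costs w_straight = 10; empty blocks,
straight pass-throughs (two opposite edges) and full four-edge crossings
are free. This is the local expression of "illuminance edges are straight;
reflectance edges need not be", and it is what keeps a short target bar
attached to its stripe even when plain-edge costs are tiny.

## Inference

MAP inference is damped min-sum (log-domain max-product) loopy belief
propagation with a fixed iteration budget:

* **original schedule** — one iteration = forward+backward sweeps along
  every row, then every column, then one message from each straightness
  clique to each of its four pixels; 6 iterations per run.
* **full-link schedule** — each iteration appends a second phase in which
  every factor→variable link (all pairwise links again plus all clique
  links) fires once in seeded random order; per-iteration message count is
  exactly 2× the sweep schedule's (asserted by a counter); 3 iterations per
  run, so both regimes spend the same total message budget.

Messages are damped (λ = 0.5), normalized to min 0, and initialized with
seeded Uniform(0, 0.1) noise. The 2×2-clique message is computed exactly in
O(K) per label by enumerating the level-partition patterns of the block;
the quadratic pairwise message uses the lower-envelope (distance-transform)
algorithm, also O(K). Belief argmin ties break toward the lower level.

**Region-shift refinement.** Short-budget loopy BP reliably discovers
*which* regions should carry their own illuminance but misjudges step
sizes, and occasionally misses a split entirely. Each run's belief-argmin
labeling is therefore polished by a monotone greedy descent on the exact
energy over three move classes: uniform shifts of constant-level connected
regions (including snapping onto a neighbour's level, which merges
regions), shifts of the part of a region on one side of a straight grid
line (which splits regions along the cheap straight edges), and
single-pixel moves. Deltas are computed incrementally over the region
boundary; the descent never increases energy.

**Run manager.** Because short-budget BP fluctuates between runs, the
decomposition kept is the lowest-energy of 30 seeded runs (10 in the noise
experiment, matching that protocol). Two deterministic reference
interpretations also compete on energy: the uniform anchored labeling
(every pixel at the lowest level keeping the image maximum within r_max)
and the per-pixel anchored labeling, both refined by the same descent.
These guarantee that the globally anchored reading and fully local reading
are always considered regardless of message-passing luck.

Everything is deterministic given the seed: run *k* uses seed + *k* for
message noise and phase-2 orders; refinement and reference starts are
deterministic.

## Stimulus generators

All figures are built on 16×16 canvases with exact palettes (no
anti-aliasing), each returning the image plus two annotated target regions.
Only the White's-effect luminances (stripes 17.5/70, targets 35 cd/m²) are
published values; all other palettes are package defaults chosen to
preserve each figure's defining ordinal structure and junction polarity
layout, and every default is recipe-configurable. Externally supplied
stimulus matrices can be used instead via `read_luminance_csv`.

Structural choices worth noting:

* White variants place a 1-px × 8-px bar centered in the dark stripe
  nearest the image centre from above; the point-mirrored bar lands in a
  bright stripe automatically. Variants change frequency (2/4/8
  cycles/image), bar length (narrow targets), bar width (tall targets,
  spanning three stripes), or palette (double increment 40/70, double
  decrement 10/30).
* The Checkershadow simplification (SCS) is a 4×4-tile checkerboard with a
  multiplicative shadow over its right part; in-shadow light tiles equal
  out-of-shadow dark tiles in luminance exactly. The shadow boundary
  crosses tile interiors, so sign-invariant X-junctions appear where it
  crosses horizontal tile edges; in the control the boundary coincides with
  tile edges and the image provably contains no sign-invariant colinear
  pair (a generator test checks this via the classifier).
* The Argyle and Snake families are implemented as checkerboards crossed by
  translucent strips — the same junction-polarity structure as the
  originals' diamond artwork, not the artwork itself. "Broken"/"control"
  variants either align strip boundaries with check edges (removing the
  transparency cue) or brighten/darken the extreme pixels (flipping
  junction polarity).
* The noise battery upsamples the SLC figure ×2 by pixel replication (no
  interpolation, so no new luminances), adds independent Uniform(±k) noise
  for k = 1..5 (clipped at 0 cd/m²: luminance is physical), then copies the
  left target onto the right so the targets are physically identical.
  Copying happens after noising, which is what guarantees identity.

## What the synthetic stimuli do and do not show

The generators produce exact-palette, hard-edged miniature stimuli — the
regime the model is designed for. They contain no anti-aliasing, no
photometric calibration error, no continuous shading, and no narrowband
noise; passing the battery therefore demonstrates the model's qualitative
predictions for classic illusion structure, not performance on photographs
or displayed stimuli. Table values for figures whose published palettes are
unknown depend on the default palettes and should be read as directions,
not magnitudes.

## Calibration and defaults

α = 0.1, β = 0.3, w_straight = 10, K = 81, λ = 0.5, init noise 0.1,
quadratic pairwise, 30 runs were fixed once against the directional
battery (White modified/original, frequency sweep, stripe grid, noised
SLC) and then frozen. At these settings the package measures: White
modified 0.491/0.438 (magnitude +0.053), original 0.438/0.438; frequency
sweep +0.053/+0.053/+0.436 (2/4/8 cycles); stripe grid zero in all
double-increment/decrement cells and positive within the frame, growing
with stripe contrast; noised-SLC magnitudes positive at every noise level
with a gently negative trend. On random 3×3 images with 5 levels, the
best-of-30 result matches exhaustive enumeration in ≥ 95 % of cases.

## Known limitations

* Magnitudes are quantized by the level grid (one step ≈ 0.05 reflectance
  at mid-gray), so nearby conditions can tie (the 2- and 4-cycle White
  figures both come out one step deep).
* The plain simultaneous-lightness-contrast split is a single step
  (+0.053), weaker than human reports; the articulated and noise variants
  produce stronger, more realistic splits.
* The checkerboard-assimilation figure is predicted flat by the modified
  model (no assimilation direction), and the original-model regime is
  unstable on it.
* Inference quality, not the energy, limits fidelity on figures with very
  low adaptive edge costs; the refinement step mitigates but does not
  eliminate this.
* No colour, no photographic input path, no T-junction machinery; variants
  that hinge on T-junction grouping are not predicted.
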