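# mirlight

Computational lightness perception on small calibrated images: `mirlight`
decomposes a grayscale luminance image (cd/m²) into an **illuminance map**
(lux) and a **reflectance map** (proportion), the way a human observer might
parse a scene into lighting and surface color — and uses that decomposition
to predict classic lightness illusions (White's effect, simultaneous
lightness contrast, the Checkershadow family, Argyle/Snake figures, Koffka
rings, checkerboard assimilation).

It is aimed at vision scientists who want quantitative, per-pixel
predictions of perceived lightness for arbitrary small stimuli, together
with generators for the standard illusion battery.

## The model

Each pixel *i* with luminance *x<sub>i</sub>* carries a discrete illuminance
variable *e<sub>i</sub>* on a log-spaced grid (81 levels over 1–10⁴ lux).
Any labeling implies a Lambertian reflectance
*r<sub>i</sub> = π·x<sub>i</sub>/e<sub>i</sub>*, so
*r·e/π = x* holds exactly for every output. A conditional random field
scores labelings with natural-scene priors:

* **unary** — lower illuminances are more likely (α·ln *e*), pixels prefer
  interpretations near the white anchor (a cost on ln(*r*<sub>max</sub>/*r*)
  for *r* < *r*<sub>max</sub>), reflectance above *r*<sub>max</sub> = 0.9 is
  penalized along a glow ramp and below *r*<sub>min</sub> = 0.03 is
  effectively excluded;
* **pairwise** — an illuminance step between 4-neighbours costs
  *w·(Δln e)²*, where *w* depends on what the luminance edge looks like:
  equiluminant pairs *w₀* = 600; sign-**invariant** colinear edges of an
  X-junction (a transparency/shadow cue) *w<sub>Xinv</sub>* = 0;
  sign-**variant** ones (typical of reflectance checkerboards)
  *w<sub>Xvar</sub>* = 50; plain edges an adaptive
  *w₁ = w<sub>Xvar</sub>·exp(−MC<sub>average</sub>)*, where
  *MC<sub>average</sub>* is the image's summed Michelson contrast per unit
  diagonal — high-contrast, articulated images are expected to contain more
  illumination change;
* **straightness** — every 2×2 block whose illuminance-edge pattern forms a
  corner costs *w<sub>straight</sub>* (illuminance edges tend to be
  straight).

MAP inference is damped min-sum loopy belief propagation under a fixed
budget — 3 iterations of a full-link schedule for the **modified** model,
6 sweep-only iterations for the **original** regime (fixed *w₁* = 20, all
X-junction pairs free), matched in total message count — with each run's
labeling polished by a monotone region-shift descent, keeping the best of
30 seeded runs by exact energy. The illusion statistic is the difference in
mean predicted reflectance between two annotated targets (left − right).

## Worked example

```python
import mirlight as ml

img, targets = ml.white_stimulus()          # 16×16, stripes 17.5/70, bars 35 cd/m²
dec = ml.decompose(img, model="modified", runs=30, seed=0)
res = ml.illusion_magnitude(dec, targets)
print(f"left {res.left_mean:.3f}  right {res.right_mean:.3f}  "
      f"magnitude {res.magnitude:+.3f}  energy {dec.energy:.2f}")
```

prints

```
left 0.491  right 0.438  magnitude +0.053  energy 194.35
```

The bar embedded in the dark stripe (left) is predicted about 5 reflectance
points *lighter* than the physically identical bar in the bright stripe —
White's effect, a partial reverse contrast: the model reads the stripes as
an illuminance grating (dark stripes ≈ one 12 % illuminance step lower), so
equal luminances imply unequal reflectances. Under `model="original"` both
targets come out at 0.438 and the illusion vanishes.

The same interface drives the experiment battery
(`ml.table1_experiment`, `ml.noise_experiment`, `ml.stripe_grid_experiment`,
`ml.frequency_experiment`, `ml.gallery_experiment`) and a CLI:

```bash
mirlight stimulus scs --out scs.csv --targets scs_targets.json
mirlight decompose --input scs.csv --model modified --runs 30 --out-prefix scs_run --png
mirlight experiment stripe-grid --model modified --seed 0 --out results/
```

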