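# Methods

## The measurement model

A short-axis B-mode view of the left ventricle shows the myocardium as an
annulus bounded by an endocardial and an epicardial ellipse (supplied as
annotations; this package never segments). With the transducer above the
image, the beam travels down the columns: the anterior (top) and posterior
(bottom) walls contain collagen/myofibers predominantly perpendicular to the
angle of insonification, the lateral (right) and septal (left) walls
predominantly parallel. Backscatter is maximal for perpendicular fibers, so
organised collagen produces a four-lobed intensity pattern around the
annulus.

The pipeline measures this pattern as the Anisotropy Index:

1. **Mid-myocardial points** — cardinal rays are cast from the centroid of
   the epicardial ellipse (the stabler manual annotation); the ROI centre is
   the midpoint between the endocardial and epicardial boundary crossings on
   each ray. Crossings are the closed-form positive roots of the ellipse
   quadratic; tests hold them to < 0.5 px against a dense parametric oracle
   (observed worst case ~2 × 10⁻³ px over 100 random annuli).
2. **ROI extraction** — axis-aligned squares of 250 µm side, converted to
   pixels as `round(side/pixel_size)` with a 1-px minimum. The window anchor
   is the pixel floor of the continuous centre; a side-`s` window spans
   `[c−(s−1)//2, c+s//2]`, so even windows extend one extra pixel down/right.
   This tie-break is fixed so results are bit-stable. ROIs clipped by the
   frame raise an error rather than silently truncating; assembly records
   them as missing (NaN), never zero.
3. **Indexes** — the four pairwise perpendicular-minus-parallel differences
   are stored signed (reproducing signed time-course plots), and the average
   index is the mean of their absolute values.
4. **Wall thickness** — endo-to-epi crossing distance per cardinal ray,
   averaged over timepoints on request (the per-position/global ambiguity is
   resolved by exposing both).

## Synthetic-data generator

The generator emulates the collagenase-perfusion experiment: isolated
arrested hearts imaged every 2.5 min for 30 min; control hearts perfused with
plain solution (n = 8) and treated hearts with collagenase for 10 or 30 min
(n = 7 each), with timepoint 0 at the solution change.

* **Intensity model.** Expected intensity at annulus angle φ (clockwise from
  anterior) is `I(φ) = I∥' + (I⊥ − I∥')·cos²φ` with
  `I∥' = I⊥ − aniso_scale·(I⊥ − I∥)`. The cos² interpolation is the simplest
  smooth, symmetric model producing the observed four-lobe pattern; only the
  two extreme levels are physically asserted. A consequence worth knowing:
  off-axis pixels inside a finite ROI sit slightly below `I⊥` (the 250-µm
  anterior ROI mean is ≈ 0.1–1 % under `I⊥` depending on annulus size), but
  the measured perpendicular/parallel gap remains exactly proportional to
  `aniso_scale`, so decay fits are unaffected.
* **Defaults** (chosen once, as realistic study conditions): `I⊥ = 40`,
  `I∥ = 10`, background 2 (gain-linear arbitrary units; the acquisition kept
  backscatter linear in gain, so no dB compression is applied by default);
  pixel size 25 µm; 384 × 384-px frames with a concentric annulus of
  epicardial radius 160 px and endocardial 80 px — a 2-mm wall, appropriate
  for an arrested rat LV. Validation studies use 160 × 160-px phantoms with
  the same 25-µm calibration (10 × 10-px ROIs), which preserves every ratio
  that matters while keeping Monte-Carlo loops fast.
* **Speckle.** Fully developed intensity speckle is multiplicative unit-mean
  exponential noise (SD = mean), drawn per pixel; Rayleigh and none are
  options, and an optional Gaussian blur (off by default) mimics a beam PSF.
  ROI means are therefore unbiased with a relative SE of `1/√N_pixels` = 10 %
  for the 10 × 10-px ROI.
* **Treatment dynamics.** `aniso_scale(t) = exp(−k·min(t, t_stop))` for
  collagenase arms (frozen at `t_stop = 10` min in the 10-min arm), 1 for
  control — the simplest monotone model consistent with the observed
  post-treatment plateau. Default `k = 0.1/min`.
* **Histology fixtures.** Pixel classes (red/orange, yellow, green,
  background) are allocated in exact counts (largest-remainder rounding) and
  shuffled. Collagen pixels are fully saturated with a zero blue channel
  (hue bins ≤ 85, defaults 20/45/60), which makes their hue provably
  invariant under the blue- and black-component subtractions; background is
  achromatic gray, which the blue subtraction removes entirely. Hue bins
  86–128 can be generated (they recover their hue directly) but are not
  subtraction-stable, because subtracting the blue channel from a pixel with
  B strictly between min and max changes its hue.
* **Orientations.** Doubled angles 2θ are drawn from von Mises(2µ, κ) and
  halved into [0, 180), the standard construction for axial data; κ is the
  concentration on the doubled circle. Per-arm defaults κ = 8 / 5 / 2 model
  increasing disarray under longer collagenase exposure; 50 measurements on
  a 10 × 5 grid per sample match the manual polarized-light protocol.

## Picrosirius-red hue classification

The classification follows the image-subtraction protocol: subtract the blue
RGB channel from all channels (removes the whitish muscle interference
color), then subtract the black component `K = 255 − max(R,G,B)` **of the
original image** (removes dark background), both clamped at 0; histogram the
result over 256 hue bins (`round(H°·255/360)`, hexcone hue; achromatic pixels
and pixels with max channel ≤ the brightness floor, default 10/255, go to
bin 0); classify bins 2–38 / 39–51 / 52–128 inclusively; content is the
percentage of *all* image pixels in 2–128 and fiber-color proportions are
percentages of the collagen pixels. The exact component semantics of the
original acquisition software are undocumented, so the standard definitions
above are used and every choice (component definitions, floor, denominators)
is config-exposed. One definitional edge: pure red (hue bin 0–1) is *not*
collagen under the inclusive 2–128 range.

## Circular statistics

Orientations are axial (defined modulo 180°), handled by angle doubling. For
a sample, `r` is the mean resultant length of the doubled unit vectors and
the angular deviation is `s = √(2(1−r))` (radians, converted to degrees):
81.03° at `r = 0` in circular space. Because the field is split on whether
the axial deviation should be reported in doubled space or halved back to
orientation space, both are emitted (`angular_deviation_doubled_deg` and
`angular_deviation_deg = doubled/2`; the uniform axial limit is then 40.51°).
Group pooling rotates each sample so its mean angle is 0° before
histogramming (5° bins, centred on zero), isolating disarray from each
heart's absolute fiber direction; unrotated pooling is available.

## Decay fitting

`fit_decay` models `index(t) = gap0·exp(−k·min(t, t_stop))`.

* `method="log"` — least squares of `log(average_index)` on the capped time,
  excluding non-positive points. Closed-form and exact on noise-free series,
  but biased low on speckled data: once the true gap falls to the noise
  level, the mean of *absolute* differences sits well above the gap (folded
  noise), flattening the log slope. Under the validation conditions this
  bias is large (median k̂ ≈ 0.07 for a true 0.1/min).
* `method="signed"` — nonlinear least squares on the signed mean pairwise
  gap `(AL+AS+PL+PS)/4`, which is an unbiased estimate of the
  perpendicular/parallel gap at every noise level. This is the estimator
  used for parameter recovery (median k̂ ≈ 0.099; ~83 % of seeds within
  ±20 %). A Fisher-information calculation for these conditions (13
  timepoints, gap-to-noise ≈ 8 at t = 0) puts the achievable sd(k̂) near
  0.015/min, so the ±20 % recovery rate sits near its theoretical ceiling
  for any estimator; larger ROIs or slower decay would raise it.

Both methods are deterministic given their inputs and return a `DecayFit`
results object with the estimates and a `summary()`.

## Validation studies and problem sizes

`myoaniso.validation` (used by `tests/test_acceptance.py` and
`scripts/acceptance.py`) regenerates everything from explicit seeds:
isotropy null band from 500 single-frame phantoms at `aniso_scale = 0` (the
absolute-value construction makes the null mean ≈ 4.6 a.u., not 0 — effects
must be judged against this band); decay recovery over 100 collagenase-30
and 100 control seeds; the 10-min-arm plateau slope against a 100-seed flat
null; a 100 × 100-px histology round trip checked bit-exactly against a
per-pixel brute-force classifier; von Mises κ = 2 recovery over 200 samples
of n = 200 (n chosen so the ~1/(2nr) bias of r̂ stays inside a 2 % check);
geometry accuracy over 100 random annuli; and a byte-level comparison of two
complete pipeline runs (1 heart per arm) with one seed.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure the analysis assumes:
two-level angular intensity modulation, multiplicative speckle, exponential
treatment dynamics, exact hue compositions, von Mises orientation scatter.
It omits physical acoustics (attenuation, refraction, beamforming, 3-D
volumes), cardiac motion (the experiment used arrested hearts), chamber
artifacts, staining variability, and manual-annotation error in the
ellipses. Passing tests therefore demonstrate that the analysis recovers
known inputs under its own model assumptions — not that those assumptions
hold in any given acquisition.

## Known limitations

* ROI squares are axis-aligned, not rotated to the local wall tangent; for
  the four cardinal positions the difference is second-order.
* The histology round trip is exact only for hue bins ≤ 85 (zero blue
  channel); real micrographs with strong blue content will lose green-range
  pixels to the blue subtraction, as the original protocol intends for
  muscle but which also affects cyan-leaning collagen.
* The decay fit assumes a single exponential with a hard stop; mixed or
  delayed kinetics would need a different trend model.
* Group inference (mixed models, multiple-testing control) is deliberately
  out of scope: the pipeline emits tidy CSVs for external statistics
  packages.
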