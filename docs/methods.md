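# Methods

## The decomposition model

A portal image from an amorphous-silicon EPID confounds two non-uniformities:
the incident beam's profile and the panel's own pixel-to-pixel gain
variation.  The vendor flood-field calibration divides both out at once,
which destroys exactly the profile information that linac and patient QA
need.  This package works with the multiplicative decomposition

    raw(x, y) = B(x, y) · S(x, y)

where `raw` is the image with the flood correction removed, `B` is the
**beam-response** (the image an ideal, uniform panel would record — beam
horns or FFF peak, panel energy response, primary-collimator corner shadow)
and `S` is the **pixel-sensitivity map (PSM)** — the per-pixel relative gain,
a property of the panel alone.  Both factors are dimensionless and normalized
to 1 on the central axis.  Knowing either factor yields the other by
division; images corrected by `S` alone keep the beam profile intact.

Coordinates are millimetres at the isocenter plane, origin at the panel
centre, crossplane = +x with column index, inplane = +y with row index.  On
even-sized axes no pixel sits on the axis, so every "central-axis value" is
the mean over the central 2x2 block (2x1/1x2 for mixed parity).

## The grid method for measuring B directly

A small (default 5 x 5 cm) field is stepped over a square grid of nodes
(default every 50 mm out to ±150 mm, 7 x 7 = 49 nodes).  Each node `p` is
imaged twice: panel centred, and panel shifted by `−p` so that the *central*
pixels sit under the field.  The sample at `p` is the mean over the central
ROI (the central block ± 5 pixels) of the **per-pixel ratio** of the shifted
image to the origin-node image.  Because numerator and denominator read the
same physical pixels, the pixel sensitivity cancels exactly, pixel by pixel
— the package's tests verify this cancellation at machine precision.  The
mean-of-ratios form was chosen over a ratio-of-ROI-means precisely because
the latter is weighted by the (unknown) sensitivities and cancels only
approximately.

A least-squares tensor-product polynomial (default degree 4 per axis, 25
coefficients against 49 samples) fitted over the node samples, evaluated on
every pixel and renormalized to the central axis, gives `B` everywhere; a
smoothing bivariate spline is available behind the same interface.  Pixels
beyond the sampled ±150 mm extent are an **extrapolation** and carry an
explicit mask; deviation statistics never pool them silently into central
ROI numbers.  The PSM follows as `S = raw_wide / B`: since the fit is
smooth, all pixel-level gain structure in the wide-field image lands in `S`,
which is the point of the method.

Numerical behaviour worth knowing:

* FFF shapes (quadratic in r) are represented essentially exactly by the
  fit; recovered-vs-truth error within ±150 mm is ~0.02%.
* Flattened shapes keep a symmetric ROI-averaging bias of order 0.1%
  (median) within ±150 mm, the same scale as the inter-node dips real
  measurements show.  The bias is even in position, so it cancels in
  symmetry ratios.
* The averaging ROI is symmetric about the *physical* panel centre (12 x 12
  pixels on an even panel, 11 x 11 on odd).  An ROI centred on pixel index
  n/2 instead sits half a pixel off-centre and masquerades as a
  ~0.0014/100 mm beam tilt — an instructive failure mode found while
  validating the symmetry benchmark.

## The simulator

The virtual linac/EPID provides ground truth for every recovery experiment.

* **Truth PSM** — product of a smooth low-frequency gain field (Gaussian-
  filtered white noise rescaled to span exactly [1−A, 1+A]; defaults
  A = 2%, correlation scale 120 mm) and per-pixel lognormal gains
  (`exp(σ·N(0,1))`, default σ = 0.5%), with a fraction (default 0.1%) of
  dead pixels zeroed and masked.  Dead pixels are never drawn inside the
  central reference region (central block + 5 px): that region anchors every
  normalization and every grid-sample denominator, so it is kept
  defect-free by construction.
* **Beams** — flattened `1 + h·(r/100)² − q·(r/100)⁴` (horns peaking
  ~90 mm off-axis) and FFF `1 − c·(r/100)²`, floored at 0.1, times a linear
  tilt `(1 + t·x/100)(1 + t_y·y/100)` and a primary-collimator factor
  (transmission 0.25 beyond 240 mm).  The library's four beams (6MV, 10MV,
  6FFF, 10FFF) use h/q/c values giving a few percent of horns and a 20–30%
  FFF fall-off at 200 mm, with the higher energy flatter (flattened) or more
  forward-peaked (FFF).
* **Acquisitions** — pixel value = B at the pixel's beam-frame position
  (panel position minus panel offset) x rectangular aperture with a 3 mm
  linear penumbra x S x dose-rate gain x i.i.d. multiplicative Gaussian
  noise (default σ = 0.1%, justified by the high short-term repeatability of
  real panels).  Every random draw is seeded; seeds for nested components
  derive from one base seed via `SeedSequence` spawn keys, making every
  experiment a pure function of its configuration.
* **Dose rate** — a single global gain `1 + s·(ref − rate)/ref` per
  acquisition; the default sensitivity 0.0036 gives +0.30% at 400 MU/min
  against the 2400 MU/min reference.  Pulse-frequency versus dose-per-pulse
  effects are not modelled.

What the simulator deliberately omits: radiation transport and energy
spectra, optical glare/spread in the panel, support-arm backscatter, panel
electronics (dark fields, saturation), and pixel-response drift.  Passing
recovery tests therefore demonstrate the *algebraic and statistical*
soundness of the calibration chain under the stated noise model, not its
robustness to those physical effects on a real panel.

## Metrics

* **Percent deviation**: `100·(target − reference)/reference` per pixel;
  pixels dead/invalid in either input or with non-positive reference are
  masked out.  The **median** is the headline statistic; mean and SD are
  reported but are dominated by edges, collimator corners and dead pixels
  when the full panel is pooled, so every record names its ROI ("central
  ±150 mm" — a 30 x 30 cm area inside the directly measured extent — or
  "full-panel").
* **Symmetry** (point-ratio convention): 100 x the maximum over mirrored
  position pairs within the region of the larger-to-smaller profile ratio,
  profiles linearly interpolated at 1 mm steps; always ≥ 100, exactly 100
  for a mirror-symmetric profile.  The evaluation region is explicit in
  every result (default half-width 140 mm, inside the fitted surface's
  direct support).
* **Flatness**: `100·(max − min)/(max + min)` over the region — implemented
  for completeness, but an aSi panel's over-response to low-energy photons
  exaggerates horns, so the number is not comparable to dose-to-water
  flatness.
* **Radial averaging** replaces each pixel by its annular-bin mean (the
  post-processing typically applied to radiation-transport beam-response
  data); ring artifacts in downstream deviation maps are its expected
  signature.

## Experiments

* **beam-dependence** — all configured beams share one truth PSM; each
  recovered PSM is compared against the first-listed beam's and against the
  truth (a simulation-only extra).
* **inter-method** — recovered PSMs per beam against an externally supplied
  reference PSM (default: the truth itself), median-first reporting.
* **dose-rate** — the grid pipeline at two rates.  The calibration chain is
  anchored at the reference rate: the grid-sample denominator and the
  wide-field raw image come from the reference-rate session (clinically, the
  flood/reference acquisition is only available at the maximum rate for FFF
  beams), and the fit/PSM extraction skip central-axis renormalization.
  Without this anchoring a purely global gain is invisible — the sample
  ratio and every renormalization cancel it — whereas with it the injected
  gain appears fully in the measured beam-response and, because S = raw/B
  with a shared raw, as its near-exact inverse in the PSM.
* **symmetry** — beams with injected tilt; the analytic beam model plays
  the perfect external profiler.  Tilt values are chosen to produce exact
  closed-form point-ratio targets.  An unsmoothed noisy external
  beam-response (truth x 0.5% pixel noise) is scored alongside to show how
  pixel noise left in a beam-response degrades the metric.

## Problem sizes and defaults

The package's default geometry is a desk-scale 238 x 238 panel over the full
400 mm active area (1/5 the linear pixel count of the full 1190 x 1190
dosimetry panel).  All structural results (cancellation, round trips,
normalizations) are resolution-independent; recovery statistics at full
scale differ only through per-pixel counting statistics.  A full grid
calibration at desk scale (98 acquisitions, fit, decomposition) runs in
well under a second; `scripts/acceptance.py` re-derives every headline
quantity in a few seconds.

## Known limitations

* The grid acquisition geometry (panel shifted by −p per node) is one
  concrete, physically consistent mechanism for sensitivity cancellation;
  real implementations may use another.  The fit family and degree are
  likewise configurable choices, not claims about any particular clinic's
  procedure.
* Deviation statistics in the extrapolated region (beyond ±150 mm) degrade
  by design and are only reported under the full-panel ROI label.
* The flood operators model a single multiplicative flood; time drift
  between flood and image sessions is not simulated.
* DICOM support is read-only (RT Image), intended for bringing real portal
  images into the native container format, and is not exercised by the
  simulation pipeline.
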