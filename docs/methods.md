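# Methods

This note documents the models, the numerical choices and the synthetic-data
design behind `palm_mcquant`, and what the passing tests do and do not show
about real data.

## Photophysical schemes

All three probes are modeled as linear first-order reaction networks under
continuous illumination; the observable is the occupancy of the fluorescent
state, peak-normalized on the evaluation grid because measured ensemble
traces are normalized to their maximum.

* **GFP**: `F → B` with bleaching rate *k_b*; `F(t) = exp(−k_b t)`.
* **tdEos** (green-to-red photoswitcher, imaged in the red state):
  `G →(k_ps) R →(k_b) B`. The closed form is
  `R(t) = r₀·e^{−k_b t} + g₀·k_ps·(e^{−k_ps t} − e^{−k_b t})/(k_b − k_ps)`,
  with the analytic limit `(r₀ + g₀ k t)·e^{−kt}` when `k_ps = k_b` (the
  degenerate case is handled by this limit, not by perturbing a rate).
* **Dronpa** (reversible switcher with bleaching from the active state):
  `dI/dt = −k_pa I + k_pda A`, `dA/dt = k_pa I − (k_pda + k_b) A`, solved by
  the 2×2 eigen-decomposition; the discriminant is non-negative for
  non-negative rates so both eigenvalues are real. `k_pda = 0` reduces to the
  tdEos cascade and is special-cased.

Both closed forms are verified against an independent Runge–Kutta integration
to 1e−9 in the tests, and mass conservation (`I + A + k_b∫A = const`) is
checked by quadrature.

### Fitting

`fit_decay` runs bounded trust-region least squares with 5 random
multiplicative restarts of the initial guess (best residual sum wins, ties to
the first start). Two parametrization choices matter:

* **A free amplitude** multiplies the peak-normalized model. Renormalizing a
  noisy trace to its own noisy maximum pins the data to 1 at an arbitrary
  sample; without the amplitude the single-exponential model is forced
  through that sample and the nested-model F-test rejects it essentially
  always, even when the kinetics are truly single-exponential. With the
  amplitude the F-test calibrates (≈5% false positives at α = 0.05).
* **Initial-state fractions** default to one free parameter (the occupied
  fraction; the complement fills the other state), which removes the
  normalization scale degeneracy. For parameter-recovery experiments the
  fractions are pinned to the generator's values: the normalized Dronpa
  bi-exponential exposes only three observables (two eigenvalues and one
  amplitude ratio), so rates and fractions cannot be fitted jointly.

Model comparison (`compare_models`) is the classical extra-sum-of-squares
F-test; the single-exponential model is nested in both multi-rate schemes.
Calibration experiments trim the time grid so the signal stays above the
noise floor — beyond it, clipping noisy fluorescence at zero leaves a
positive-mean tail that any slow extra component absorbs, an artifact of the
data treatment rather than of the kinetics.

`rate_vs_intensity` is ordinary least squares of fitted rate on illumination
intensity; the intercept is flagged non-zero when it exceeds twice its
standard error, the signature of spontaneous (light-independent) switching.

### Recovery experiment design

Defaults: tdEos g₀ = r₀ = 0.5, time grid 0–60 s (200 points); Dronpa
i₀ = 0.7, a₀ = 0.3, grid 0–250 s (250 points, long enough to resolve the slow
eigenvalue ≈ 0.017 s⁻¹ at the reference rates); additive Gaussian noise,
sd 0.01 of the peak. The Dronpa pool is deliberately only partially
pre-activated: with a fully active pool the slow eigenmode's amplitude
(≈0.009 of the peak) sits below the noise floor and the switching rates leave
no usable signature in the trace — an uninformative design under which no
fitting method could recover them.

## Synthetic acquisition and localization

`simulate_stack` emulates EMCCD PALM acquisition: 160 nm pixels, 120 nm PSF
standard deviation (≈0.75 px, comfortably above the half-pixel sampling limit
that the generator enforces as a hard error), 1000 photons per activation
event, flat background of 10 counts, optional smooth uneven background (a few
broad Gaussian bumps), per-pixel Poisson draws. Blinking is memoryless: one
activation probability per emitter per frame; real photoswitching dwell-time
correlations are deliberately out of scope (ensemble kinetics are modeled
separately).

The localization chain per frame:

1. **Background**: subtract the frame mean (even part), then subtract the
   grayscale morphological opening with a radius-1 disk (uneven estimate) and
   clip at 0.
2. **Detection**: 8-connected components of pixels above T2 = 0.7·T1 that
   contain at least one pixel above T1; accepted iff ≥ 3 pixels above T2
   (rejects single shot-noise pixels) and ≤ 30 pixels above T3 = T1 (rejects
   objects too bright/extended for one molecule). T1 defaults to 5·√background
   (the 5σ shot-noise rule); the count thresholds are configurable.
3. **Fit**: symmetric 2D Gaussian (amplitude, x, y, sd, offset) on the padded
   bounding box of the mean-subtracted frame, initialized at the candidate's
   center of mass, with residuals weighted by 1/√(counts + background
   variance). Unweighted least squares on Poisson data proved measurably
   inefficient (median error ≈1.4× the Thompson prediction; weighted ≈1.2×).
   Non-convergent fits and centers leaving the crop are discarded.
4. **Uncertainty**: Thompson photon-statistics formula with the background
   term, `var = (s² + a²/12)/N + 8π s⁴ b²/(a²N²)`; photons are the fitted
   Gaussian volume divided by the camera gain (default 1).

Coordinates are continuous nm with half-open pixel membership (pixel *k*
spans [k·s, (k+1)·s), center at (k+0.5)·s).

**Rendering** places each molecule as a unit-integral Gaussian with sd equal
to its localization uncertainty, integrated over pixels (erf) and truncated
to the 5×5 PALM-pixel block centered on the coordinate's pixel; the kernel is
not renormalized after truncation, so image mass equals the summed truncated
kernel masses, and background pixels are exactly zero. PALM pixel default:
20 nm.

## Colocalization

Mander's coefficients use strict positivity for co-occupancy, which is exact
on rendered images because their background is identically zero. Category
cut-offs are strict inequalities (values at exactly 0.33/0.66 fall to
partial). MC pairs form by mutual nearest-neighbor centroids within a
distance cap (500 nm default); each pair is evaluated on the union bounding
box of its two masks dilated by 2 PALM pixels; unpaired clusters are
evaluated on their own dilated box and normally land in the isolated
category. Category fractions are reported among pairs with both coefficients
positive (they sum to 1), with the isolated fraction computed separately over
all analyzed MCs. Periphery membership uses the pair's mean centroid
normalized radius in [0.7, 1.0].

## Ripley analysis

The estimator excludes self-pairs, uses strict `d < r`, and weights each
ordered pair by the Haase factor: the fraction of the circle through the
neighbor, centered on the focal point, inside the rectangular window —
computed analytically (edge arcs minus corner-overlap corrections) and
validated against dense arc sampling. Pair finding uses a k-d tree; the
per-radius reduction is `math.fsum` over individual pair contributions, i.e.
the correctly rounded sum, so the result is bit-identical to a brute-force
double loop regardless of enumeration order.

CSR significance: 300 Monte-Carlo patterns by default; the band
`CI₉₉ = 1.68·√A/n` normalizes L(r) − r to ±1. This critical value bounds the
supremum of the statistic over r, so pointwise coverage at a single radius
sits near 100% rather than 99% — the calibration test's band accounts for
that. `r_max` is the grid radius of the first global maximum of L(r) − r
(ties to the smallest r) and a sentinel (`None`) when the curve never goes
positive. The default grid is 0 to min(500 nm, a quarter of the shorter
window side) in 10 nm steps; analyses of large-radius clusters pass an
explicit longer grid, since for uniform-disk clusters the L(r) − r peak falls
between one and two true radii (r_max is a domain-scale summary, not an
unbiased radius estimate — its monotone response to the true radius is what
the tests pin down).

Cluster segmentation: 8-connected components of nonzero rendered pixels,
area-thresholded (default 50 PALM px²) to remove unclustered single
molecules; centroids are intensity-weighted.

## Morphology

The Benkrid perimeter is the closed Moore-neighbor (8-connected) boundary
trace through edge-pixel centers with link lengths 1 (straight) and √2
(diagonal); single-pixel-wide spurs are traversed twice, as a doubled path.
Degenerate masks use outer-boundary conventions: a single pixel counts 4, a
1×2 domino 6; such shapes are normally removed by the area threshold anyway.

A known property of chain-code perimeters: they overestimate smooth contours
by ~4–5% asymptotically, so the circularity of rasterized disks plateaus
near 0.91 rather than converging to 1, while very small disks gain a
compensating area overshoot (C(r=10) ≈ 0.99). Circularity is therefore not
monotone in disk radius; both ends stay within 0.15 of 1 and a radius-30
disk lands within 10% of the ideal circle.

Cell geometry defaults to the minimum enclosing circle of the thresholded
TIRF footprint (manual center/radius can be supplied). Normalized radius
clips values > 1 to 1 with a warning. Radial circularity profiles use bin
width 0.25 (centers 0.125 … 0.875), report empty bins as missing rather than
zero, and intensity profiles normalize to their maximum (default bin width
0.05 for localizing profile peaks).

## What the synthetic tests do not show

The generators use ideal Gaussian PSFs, memoryless blinking, Poisson-only
noise (no EM-gain excess noise or read noise), perfectly registered channels
and sharply bounded uniform-disk clusters. Passing tests demonstrate the
correctness and calibration of the estimators under these conditions; they
do not certify detection thresholds, pairing caps or area thresholds for a
specific microscope, which must be re-tuned on real acquisitions (drift,
chromatic offsets and autofluorescence are explicitly out of scope).

## Problem sizes

Default experiment sizes were chosen so each analysis is statistically
informative yet quick: 100 traces per recovery experiment, 1000-frame stacks
(~2500 events), 2000 CSR patterns of n = 500 for band coverage, 10 seeds per
cluster radius for r_max, 20 random patterns for oracle-equality checks.
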