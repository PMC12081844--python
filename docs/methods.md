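# Methods

This note records the models behind `qpid`, the defaults and why they
hold, what the synthetic-data generator does and does not emulate, and
the numerical choices a maintainer would want to know.

## Detector and data model

The pixel detector is modelled as a 256 × 256 grid at 55 µm pitch
(1.4 × 1.4 cm² field of view), reporting per-pixel time of arrival on a
1.5625 ns quantum and deposited energy in keV after an affine
time-over-threshold calibration. The gamma channel reports event time and
digitizer pulse area; a single multiplicative constant (fixed from a
known photopeak, e.g. annihilation at 511 keV) converts area to keV.
Coordinates are 0-based `(col, row)` with the origin at the top-left
pixel; centroids are fractional pixel units and physical positions are
`(index + 0.5) × 55 µm`. All list-mode I/O goes through a transparent
tab-separated dialect (`#qpid-listmode v1`) because the vendor binary
formats are proprietary; quantitative images are float32 TIFF plus a JSON
sidecar, and any log₁₀(1+x) scaling is a separate display-only rendering.

## Track aggregation

Two hits link when |Δt| ≤ the aggregation window (default 40 ns) and
their Chebyshev pixel distance is ≤ 2 (bridging diagonal steps and single
dead pixels; the threshold is configurable since "near-adjacent" is not
otherwise pinned down). Tracks are connected components of this graph,
computed with union-find over a time-sorted sliding window, so the
partition is independent of input order and a track may span more than
one window end-to-end through chained links. Consequences to be aware
of: two true particles overlapping in space and time are merged (pile-up
is not resolved), and no cap is applied to total track duration.

## The synthetic source

The generator reproduces the statistical structure the pipeline assumes,
not particle physics:

* **Decays.** Per-source Poisson counts (activity × duration), uniform
  decay times. Chains are walked per decay. The bundled chain table keeps
  only each nuclide's dominant path and line so that one ²²³Ra decay
  yields exactly 4 α + 2 β⁻ to stable ²⁰⁷Pb, one ¹⁸F decay one β⁺, one
  ²²⁷Th decay 5 α + 2 β⁻; ⁸⁹Zr splits 0.77/0.23 between the 12.7 keV
  Auger branch and a β⁺ branch (mean 395.5 keV, endpoint 902 keV).
  Minor real-world branches (e.g. the ~0.3% ¹⁸F electron capture, the
  ²¹¹Bi β branch) are dropped; half-lives and energies are standard
  nuclide-chart values stored as editable YAML package data.
* **Chain timing.** By default daughters decay at the parent decay time
  (prompt approximation). Because all emissions of a decay then share a
  position and time, they merge into one piled-up track downstream —
  acceptable for counting, wrong for per-particle PID. The ingrowth mode
  (`prompt_chain=False`) samples each daughter's exponential lifetime and
  drops emissions past the acquisition end; use it whenever tracks must
  correspond one-to-one with emissions.
* **Beta spectra.** A surrogate endpoint-scaled Beta(2, b) distribution
  with b matched to the tabulated mean energy. Shape is plausible, not
  evaluated against Fermi theory.
* **Mylar.** Each α loses a uniform draw from 1.5–2 MeV. This range is a
  statement about the film, not about per-particle straggling, so
  simulated α lines are ~500 keV-wide blocks (~400 keV after
  saturation) — far wider than real straggled peaks. Overlapping chain
  lines therefore cannot be separated in a merged spectrum; measured peak
  positions for the α calibration are taken per line / per source
  (centroid of each single-line spectrum), matching the use of individual
  calibration sources.
* **Saturation.** Measured α energy is `E` below a 3 MeV knee and
  `0.8·E + 0.6 MeV` above it (continuous, slope < 1) — the
  under-reporting the secondary calibration must undo. On by default.
* **Track shapes.** α: filled disc with diameter ~ N(450 µm, 40 µm)
  (floored at 3 pixels) and a truncated-Gaussian radial energy profile
  (σ = radius/2); pixel energies renormalize to the measured energy
  exactly, also when the disc is clipped at the grid edge. β/Auger:
  self-avoiding persistent random walk of `L(E) = round(0.21·E^0.77)`
  pixels (12.7 keV → 1 pixel, 900 keV → ~40 pixels), Dirichlet(5) energy
  split. The exponent is a morphology surrogate, not a range-energy
  claim.
* **Timing.** Per-hit jitter is Gaussian(σ)+Exponential(τ) with σ = τ,
  scaled so the analytic exponentially-modified-Gaussian FWHM equals the
  configured intra-track target (default 7.7 ns) — right-skewed, as the
  measured residual distribution is. Gamma coincidence jitter is Gaussian
  with FWHM equal to the CTR target (default 24.2 ns); the ~15 ns flat
  top seen on the real device is not reproduced. Hit times are quantized
  to 1.5625 ns and clipped at 0.
* **Gamma channel.** Each *detected* positron yields a 511 keV event
  (4% Gaussian smear) with the configured coincidence probability
  (default 0.023, the measured coincident-method efficiency); background
  singles are Poisson at a configured rate (default 0 — the real room
  background depends on the installation) with uniform energies.
* **Acceptance.** Isotropic directions; emissions with a sensor-ward
  direction cosine are kept (2π acceptance → 0.5). No absorption or
  edge-of-sensor losses beyond that.

A green test on synthetic data therefore establishes that the pipeline
implements its stated rules correctly — not that the device physics
(charge sharing, straggling, dead time, readout saturation) is captured.
The linearity-range rolloff of the real readout is likewise not part of
reconstruction; saturating inputs can be emulated when fitting.

## Coincidence and randoms

Matching considers all track–gamma pairs with |Δt| ≤ 60 ns, assigns
greedily in order of increasing |Δt| (earlier track wins exact ties), so
each gamma tags at most one track and each track stores its nearest
available gamma — deterministic and one-to-one to avoid double counting
in β⁺ images. The randoms estimate `r₁·r₂·τ` uses the full window width
τ (not 2τ): that convention reproduces the printed operating-point
arithmetic (0.0006 events/s; SNR 1.7 × 10⁴ at 10 events/s true;
SNR 0.1 at a 10 ms window).

## Particle identification

Defaults: β upper threshold 1 MeV, α lower threshold 3 MeV (applied to
factory-calibrated energy, *before* the secondary α transform —
identification precedes correction), annihilation-gamma threshold
450 keV, circularity = elongation ≥ 0.6 AND hull-fill ≥ 0.6. Elongation
is √(λ_minor/λ_major) of the energy-weighted second-moment matrix; fill
is n_pixels over the filled convex hull's pixel count; a single-pixel
track is (1, 1) by convention. The circle-versus-line statistic is the
minimal realization of the stated filter; the thresholds themselves do
most of the separation (5–8 MeV discs vs ≤ 1 MeV walks are > 99%
separable by energy alone). β⁻ vs β⁺ is decided only by gamma
coincidence. Energy-window bounds are inclusive (the 5–20 keV Auger
window keeps a track at exactly 20 keV).

## Calibration

The factory ToT→keV calibration is surrogate-affine (global or
per-pixel with a median fallback). The α transform is a strictly
increasing piecewise-linear interpolant through matched
(measured, reference) peak pairs with linear end-segment extrapolation —
exactly invertible over the distortion family the simulator produces
(affine above the knee). Fitting on ²³⁹Pu/²⁴¹Am/²⁴⁴Cm (5.144/5.485/5.804
MeV) and validating on held-out ²²³Ra/²²⁷Th chain lines recovers peaks to
< 2% (see the per-line peak measurement note above). Applying the
transform to a β-labeled track is a contract violation.

## Images and measurements

Increment rules are as stated in the README; centroid binning is the
floor of the fractional coordinates (no sub-pixel spreading). mm²
normalization uses the pixel area (55 µm)² = 3.025 × 10⁻³ mm². Dead
pixels (optional mask) are skipped in event maps and centroids are moved
to the nearest unmasked pixel. Profile FWHM interpolates linearly at half
maximum using the outermost crossings; ROI statistics report mean ± SEM
(SEM chosen and labeled; SD is recoverable via n_pixels).

## Deconvolution and uncertainties

The activities minimize the printed unweighted sum of squares, with a
non-negativity constraint added (activities cannot be negative);
unconstrained mode exists for oracle-equality checks and both agree
whenever the unconstrained solution is non-negative. A Poisson-weighted
variant is deliberately not the default so the printed formula is the
reference behaviour. Reported 1σ uncertainties are parabolic, from the
quadratic form at the minimum with per-bin Poisson variances taken from
the fitted model (the heteroscedasticity-consistent covariance of the
unweighted estimator). The naive unit-variance Hessian error is badly
miscalibrated on counting data (measured ~30–40% coverage where ~68% is
nominal); the adopted convention measures 60–75% coverage on Poisson
replicates. MINOS-style asymmetric intervals are not computed.
Collinear bases raise an error carrying the condition number (limit
1e8).

## Width estimation

FWHM/FWTM use linear interpolation between bin centers at half/tenth of
the peak count, with the outermost crossings, so flat-topped shapes count
the plateau toward the width. On sampled Gaussians the estimates match
2√(2 ln 2)σ and 2√(2 ln 10)σ within binning error; residuals about a
per-track mean of n hits shrink by √(1 − 1/n).

## Reproducibility

Every stochastic operation takes a seed or `numpy` Generator; the
pipeline derives per-stage sub-seeds from one master seed via
`SeedSequence.spawn`, and identical seeds give byte-identical list-mode
files, truth tables and reports.

## Known limitations

* No charge transport, energy straggling, delta rays, or Monte Carlo
  geometry — the generator is a morphology/statistics surrogate.
* Pile-up merging is unresolved; prompt-mode chains exaggerate it.
* No clock-drift model between the two streams (hardware-synchronized in
  the real device).
* Tissue attenuation, dose conversion, and brightfield co-registration
  are out of scope; the bioequivalence tooling operates on
  already-measured activities.
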