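# Methods

## Overview

The pipeline estimates dsDNA binding affinity from laser-induced
dissociation in LILBID mass spectrometry. Per droplet it measures (i) the
explosion width from a camera snapshot, a proxy for transferred laser
energy, and (ii) the dissociated fraction % ssDNA from the ToF spectrum.
Per run it fits the linear width–dissociation trend inside a region of
interest and interpolates at a fixed reference width; across samples it
calibrates that readout to solution-state affinities with York
errors-in-both-variables regression.

## Explosion-width measurement

Images are 2×2 binned by block **averaging** (summing would rescale
thresholds), thresholded manually, reduced to the largest 8-connected
component, and cut to the **top fraction** (default 0.5) of that
component's bounding-box height; the width is the Feret (maximum caliper)
diameter of the remainder.

Choices that fix reproducibility:

* The Feret diameter is computed on **pixel corner** coordinates (convex
  hull, then max pairwise distance), so a single pixel has extent √2·pitch
  and results are bit-exact. An exhaustive corner-pair search is kept as
  the test oracle.
* "Top part" of the plume is not a physically derived quantity; it is a
  configurable fraction of the component bounding box, recorded in every
  output row together with the threshold.
* The binned pixel pitch is exactly 2× the raw pitch (30 µm at the 15 µm
  camera resolution); the reported per-droplet width error equals one
  binned pixel, since discretisation, not statistics, dominates.

## Spectrum processing

Fixed stage order: **calibrate → smooth → linearize → integrate**.

* *Calibration*: two (time, m/z) calibrant points fix the ToF law
  m/z = a(t − t₀)² (√(m/z) linear in flight time). Points at t ≤ t₀,
  where the law is non-monotone, are dropped. Which calibrants to use is
  the caller's choice; for synthetic runs the generator supplies its two
  singly charged peak apexes.
* *Smoothing*: moving average over a **full width** of 20 m/z (the window
  could also be read as a half width; full width is implemented and
  flagged here). At the spectrum edges the window shrinks symmetrically so
  the mean stays centred.
* *Linearization*: linear interpolation onto a uniform grid, default step
  1.0 m/z (a convention; configurable), spanning only the input range.
* *Peak integration*: for each species the background anchors are the
  intensity minima flanking the theoretical [M − zH]ᶻ⁻ position within a
  search halfwidth (default 700 m/z); the net area is the trapezoidal
  integral minus the trapezoid under the straight chord joining the two
  anchors. For overlapping peaks the shared valley minimum becomes the
  inner bound of both. Negative net areas are clipped to zero and flagged.
* *% ssDNA* uses the singly charged 35mer⁻ and dsDNA⁻ peaks by default
  (higher charge states overlap for some samples); the multi-charge sum
  is available and validated on the two-charge synthetic case. Equal
  relative response of the two species is assumed throughout.

## Dissociation curves

Widths and % ssDNA are inner-joined on droplet index; orphans are logged,
never silently dropped, and duplicate indices are an error. The analysis
is defined on the ROI **620–1200 µm inclusive** (above ~1200 µm an
instrumental signal decay confounds the trend; those droplets are simply
excluded, not modelled). The ROI points are fitted by **unweighted OLS**
(per-droplet % ssDNA errors are not available) and evaluated at
**1100 µm**. The reported uncertainty is the standard error of the fitted
mean, s·√(1/n + (x₀ − w̄)²/Sxx) — the uncertainty of the interpolated
point, not a prediction interval for a new droplet. Replicate runs are
summarised as mean, sample s.d. (n−1) and s.e.m.

## Calibration models

Training data pair each duplex's % ssDNA at 1.1 mm (x) with its UV T_m or
log10 K_d (y). Printed tables give s.e.m. with replicate counts; York
weighting uses s.d. = s.e.m.·√n. K_d values are converted from nM to molar
before log10; the s.d. of log10 K_d comes from the delta method,
sd(K_d)/(K_d·ln 10) — the transformation is not prescribed anywhere, so
this standard choice is made explicit here. The T_m model trains on the
nine designated model duplexes; the log K_d model on the seven of those
with ITC values (two binders exceed the ITC range).

York iteration: weights ωx = 1/sx², ωy = 1/sy²; combined weights
Wᵢ = ωxωy/(ωx + b²ωy − 2br√(ωxωy)); slope initialised at OLS and iterated
to |Δb| < 1e-10 (max 500 steps; the fits here converge in < 10).
Correlation r = 0 throughout. Standard errors follow the York (2004)
adjusted-x variance expressions. Degenerate limits (sx→0: weighted OLS of
y on x; sy→0: inverse regression) are enforced by tests against closed
forms.

**Confidence bands** use var(ŷ(x)) = χ²ᵣₑ𝒹·(1/ΣW + (x − x̄w)²·se_b²) with a
Student-t quantile at n−2 df. Scaling by the reduced goodness statistic is
a design choice: it makes the band collapse for residual-free data and
behaves like standard regression inference (near-nominal Monte-Carlo
coverage) when the stated errors are realistic. The fit's reported
slope/intercept standard errors are the unscaled York values.

Predictions use the unrounded fitted coefficients; evaluating outside the
training x-range raises an extrapolation warning (the three held-out
samples sit slightly outside it, which is inherent to the benchmark). A
cross-model (York fit of log K_d on T_m over the seven paired duplexes)
provides the solution-state-only baseline; it is validated qualitatively
(sign, ordering, agreement to a few tenths of a log unit), since exactly
how its reference values were weighted is not documented.

**UV melting temperatures** are the temperature of the maximum first
derivative of absorbance: optional boxcar smoothing, central differences,
then a parabolic refinement through the three points around the discrete
maximum. A derivative maximum on the curve boundary means no transition
was captured and is an error.

## Synthetic droplet events

The generator emulates the statistical structure the pipeline relies on,
not droplet physics (no IR absorption, shock-wave, or desorption
modelling):

* **Images**: a filled-ellipse crown over a vertical stem on a noisy dark
  background, 16-bit grayscale. The crown's semi-axis is chosen so the
  *measured* caliper (after binning, thresholding, top-region selection
  and corner Feret) lands within one binned pixel of the requested width;
  a −0.4 px rasterisation offset centres the round-trip error (empirical
  max |error| ≈ 20 µm over 400–1600 µm).
* **Spectra**: Gaussian peaks (σ = 50 m/z) at the [M − zH]ᶻ⁻ positions of
  the 35mer (10 823 Da) and duplex (13 827 Da), areas split equally across
  charge states with 100·A_ss/(A_ss+A_ds) = pct_ss exactly in the
  noiseless limit; constant baseline (5) plus additive Gaussian noise
  (sd 2) per sample; sampling uniform in flight time under the generator's
  ToF law so linearisation is exercised. Beyond 1200 µm total peak
  intensity decays exponentially (e-folding 250 µm), emulating the
  ion-optics signal loss; the ratio, and hence % ssDNA, is unaffected.
* **Truth law**: % ssDNA(w) = clamp(0.07·w − 17, 0, 100), i.e. 60% at the
  1.1 mm reference — a mid-affinity duplex. Widths are uniform over
  400–1600 µm, 300 droplets per run (the per-curve droplet count of a
  real run). Per-droplet realised % ssDNA adds Gaussian scatter of sd 4
  percentage points about the truth line before spectrum synthesis:
  droplet-to-droplet variability is visually evident in real curves but
  uncharacterised, so this magnitude is a convention chosen once to make
  end-to-end recovery a meaningful test rather than a numerical identity.
* Everything is reproducible bit-exactly from (config, seed); per-droplet
  child seeds are spawned from the run seed.

What passing tests therefore show: the *chain* of estimators is unbiased
and correctly propagates a linear dissociation law through imaging and
spectral processing at realistic noise. What they do not show: robustness
to real-instrument features the generator omits — non-Gaussian peak
shapes and buffer-adduct tails, baseline drift, unresolved charge-state
overlap, plume morphologies without a clean crown, or correlated
width/intensity fluctuations.

## Problem sizes and numerical conventions

Simulated runs use 300 droplets (≈ 145 inside the ROI), matching a real
dissociation curve; replicate demonstrations use five runs of 100
droplets. Monte-Carlo checks use 50 replicates (melting curves) and 1000
replicates (confidence-band coverage at n = 8). York tolerance 1e-10;
OLS oracle agreement 1e-9; Feret oracle exact. Degenerate inputs error
loudly: empty masks, all-background thresholds, identical widths,
all-zero peak areas, monotone melting curves, zero York error bars
(unless a caller-supplied floor is applied).

## Known limitations

* The calibration models are only as good as the printed reference table:
  its means and s.e.m.s are rounded, which visibly perturbs the fitted
  coefficients in the second decimal.
* The % ssDNA readout assumes equal response factors for ss and ds
  species; no response-factor correction is implemented.
* The ROI and reference width are fixed conventions of the method, not
  re-derived from the data; samples whose dissociation saturates near 0%
  or 100% inside the ROI violate the linearity assumption (the fit value
  is clipped and flagged, not remodelled).
* ITC isotherm fitting and theoretical nearest-neighbour T_m prediction
  are out of scope; those values are consumed, not computed.
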