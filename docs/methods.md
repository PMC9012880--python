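# Methods

`capspec` quantifies microvascular function from two complementary optical
measurements of thin, transilluminated skeletal muscle: dual-wavelength
intravital video microscopy of individual capillaries, and continuous-wave
transmission spectroscopy (CWS) of the tissue volume.  Because the
acquisitions it targets are not publicly deposited, every analysis component
is validated closed-loop against a forward simulator with complete ground
truth.  This note records the models, the parameter choices, and what the
simulator does and does not capture.

## Optical model

All signals are expressed as optical density, `OD = log10(I0 / I)`, which
under Beer–Lambert equals `ε(λ) · L · C` with `ε` the hemoglobin extinction
coefficient (mM⁻¹ cm⁻¹), `L` the optical path (cm) and `C` the hemoglobin
concentration (mM).  Two wavelength roles matter:

- **Isosbestic wavelengths** (452, 500, 530, 545, 570, 584 nm in the
  visible; 450 nm for the video camera), where `ε_oxy = ε_deoxy`.  OD there
  is independent of oxygen saturation and tracks hemoglobin *content*.
  Time series are reported as `ΔOD(t) = log10(I(0)/I(t))`, the change
  relative to the first sample, so rising hemoglobin gives rising ΔOD.
- **An O₂-dependent wavelength** (438 nm).  The per-red-cell OD ratio
  `R = OD438/OD450` is affine in saturation between two calibration
  endpoints: `SO₂ = (R − R_deoxy)/(R_oxy − R_deoxy)`, clipped to [0, 1].
  The instrument calibration constants are not public; the package defaults
  (`R_oxy = 1.2`, `R_deoxy = 0.6`) are placeholders used symmetrically by
  the simulator and the analysis, and are configurable.

The bundled extinction table carries approximate literature-scale values at
the eight working wavelengths; the 438-nm oxy/deoxy entries are constructed
to be consistent with the default calibration ratios.  Absolute hemoglobin
quantification is out of scope, so only ratios and *changes* of OD matter,
making the analysis insensitive to the absolute scale of these entries.

The 2-nm spectrometer bandpass is realized as the unweighted mean of the
spectral grid samples within λ ± 1 nm inclusive.  The six isosbestic ΔOD
series are averaged without weights; uncorrelated per-band noise falls by
≈ √6 (verified by simulation).

## Forward simulator

`synth.SimulationConfig` defaults mirror the acquisition geometry: 696 × 520
px at 0.6466 µm/px (450 µm across the width), 12-bit counts, 21 frames/s for
60 s at 438/450 nm; CWS covers 450–650 nm at ~10.5 jittered recordings/s for
120 s (≈ 1260 profiles; exactly 1200 at 10/s).

Red cells are rendered as 6 × 5 µm anti-aliased rectangles (invented
geometry) moving single-file along a centerline with jittered
center-to-center spacing (default 20 µm, truncated above 1.2 × cell length),
separated by plasma gaps at the tissue background intensity.  Tract OD at
450 nm follows Beer–Lambert from the cell's path (5 µm) and hemoglobin
content (11.1 mM, chosen to give OD ≈ 0.35); OD at 438 nm is the 450-nm OD
times the calibration ratio at the programmed SO₂.  Camera noise is additive
Gaussian (default σ = 7 counts ≈ 1% of the tissue background) rather than
full photon shot noise — simpler, and sufficient for recovery testing.  CWS
noise is shot-like (σ proportional to intensity, default 0.5%).

Vasomotion is a single sinusoid on the tissue hemoglobin concentration,
`C(t) = C₀(1 + m sin(2πt/T + φ))`, with default period 28.8 s and depth
m = 0.05 (ΔOD₄₅₀ amplitude ≈ 0.03, in the range of the low-frequency
oscillations the pipeline is meant to detect).  By default the same factor
modulates capillary velocity in phase, reflecting the observed synchrony of
hemoglobin and flow oscillations; the coupling can be switched off.

Flow programs: steady; intermittent (velocity gated by a square wave with
4-s stops — deliberately beyond the 3-s intermittency rule); reversed
(sign alternating every 5 s); stopped.  Ground truth records per-frame
velocity, lineal density, supply rate, SO₂, and boundary-crossing counts
(cells entering = cells exiting + change in residents, used as a
conservation check).

The simulated cohort is 2 groups (control / peritonitis) × 5 animals × 8
fields of view × 3 imaging periods.  Control fields never oscillate;
peritonitis fields oscillate from period 2 onward with per-field periods
drawn uniformly in 16–32 s, except a 25% fraction left non-oscillatory to
mimic the spatial heterogeneity of microvascular dysfunction.  Cohort
records carry spectroscopy by default; video rendering is optional
(`include_video=True`) because the hemoglobin-oscillation endpoint is
spectroscopy-derived and full-frame video for 240 field-periods is
disproportionate.

**What the simulator does not capture:** motion artifacts and focus drift,
light scatter, vignetting, non-sinusoidal or drifting vasomotion, capillary
tortuosity in depth, cell shape and deformation, and correlated noise.
Passing closed-loop tests therefore demonstrates correctness of the
algorithms under the stated optical model, not robustness to every property
of real recordings.

## Space–time image analysis

An STI is built per capillary and wavelength by bilinear sampling of each
frame at equal arc-length steps along the centerline (default step = one
pixel); rows are positions (arteriolar end first), columns are frames.

- **Incident intensity / tract mask.**  The incident (plasma-gap) surface is
  the 90th-percentile intensity over ~1 s × ~10 µm blocks, bilinearly
  interpolated back to full resolution (a fast approximation of a rolling
  percentile).  The STI divided by this surface is thresholded with Otsu's
  method; STIs with < 3% relative contrast are declared tract-free with a
  warning.  Components smaller than 5 px are discarded as noise.
- **Velocity.**  Per non-overlapping 0.5-s window of the masked absorbance
  STI, adjacent-column cross-correlations (zero-padded FFT) are summed and
  the correlogram peak gives the displacement in rows per column at
  sub-pixel (parabolic) precision; a narrow Radon-style search maximizing
  the variance of the shear projection refines it.  Velocity =
  displacement × position_step / time_step, signed positive
  arteriolar→venular; ties prefer the smaller |velocity|.  A flat angle grid
  was considered and rejected: on 0.5-s windows its resolution collapses at
  steep tract angles (> 15% error at 500 µm/s), whereas the two-stage
  estimator recovers 50–500 µm/s with < 1% median error.  Windows with no
  tracts, or |v| < 10 µm/s with absorbance-centroid displacement < 2 px
  across the window, are assigned exactly 0 (stopped); the thresholds are
  configurable.
- **Tract identity.**  Plain connected components fragment any tract moving
  faster than one position step per frame (≳ 14 µm/s), so labelling is done
  in displacement-compensated coordinates: columns are sheared by the
  integrated estimated velocity, labelled, and mapped back.
- **Lineal density** counts the maximal vertical mask runs per column
  (partial tracts at segment ends included) divided by segment length;
  **hematocrit** converts it with
  `Hct(%) = 100 · LD · V_rbc / (π (d/2)² · 1000)` using rat defaults
  V_rbc = 55 fL and d = 5 µm (invented, configurable);
  **supply rate** is `|v| · LD / 1000` with stopped frames forced to 0.
- **SO₂** per tract uses the 450-nm mask on both wavelength STIs, the mean
  tract and incident intensities for the ODs, and the calibration above.

## Flow classification and functional capillary density

Over a 30-s window: *stopped* if velocity is identically 0; *intermittent*
if any maximal zero run is strictly longer than 3 s (an exact 3.0-s stop
does not qualify) or if both flow directions are sustained ≥ 0.5 s (the
0.5-s persistence suppresses single-window sign noise); otherwise
*continuous*.  Functional capillary density is the count of capillaries
crossing three horizontal lines (at ¼, ½, ¾ of frame height) divided by
3 × field width; a capillary crossing two lines counts twice, and each
capillary counts at most once per line.

## Spectral analysis

ΔOD series are resampled to a uniform grid (default 10.5 Hz, linear
interpolation) when timestamps are jittered.  The power spectrum is the
squared one-sided amplitude spectrum of the mean-removed series,
`A_k = 2|X_k|/N` (DC/Nyquist not doubled), so a sinusoid of amplitude A
carries Power A² in its bin; no taper and no zero-padding by default (both
exposed as options).  Mean frame intensity (1 min at 21 fps) and CWS (2 min
at ~10.5 Hz) series are analyzed at native length.  The vasomotion band is
0.03–0.06 Hz (16–32 s), edges inclusive; the band peak is the maximum Power
over in-band bins, ties to the lowest frequency.  A 120-s record gives
Δf ≈ 0.0083 Hz, i.e. 4 bins in the band; at least 64 samples and one in-band
bin are required.

## Statistics

- **ROUT outliers (constant model).**  Robust center by iterated
  Lorentzian-weighted mean; robust scale RSDR = 68.27th percentile of
  absolute residuals × n/(n−1); residual ratios |r|/RSDR are converted to
  one-tailed P values against a standard-normal reference and screened with
  a Benjamini–Hochberg threshold at level Q (default 1%).  The normal
  reference and single tail are this package's convention: on clean normal
  data (n = 40) the measured false-positive fraction is ≈ 0.2% (well below
  2Q), while a 5σ-displaced point is flagged in ≈ 99% of runs; a two-tailed
  t reference drops detection to ≈ 88% with no practical false-positive
  benefit.  Q = 0 is accepted as the degenerate limit (nothing flagged).
  Values are screened within each imaging period.
- **Matched-field exclusion.**  A field of view flagged in any period is
  removed from all periods, preserving repeated-measures matching; the
  operation is idempotent and removal counts are logged.
- **Two-way ANOVA.**  Fixed-effects group × period model via type-III sums
  of squares with sum-to-zero coding (statsmodels OLS), robust to mild
  unbalance from exclusions; on balanced tables it agrees with the textbook
  decomposition to machine precision (tested against an independent
  brute-force oracle).  Post-hoc per-period group contrasts use the pooled
  residual variance; raw P × 3 (Bonferroni over the three periods), capped
  at 1.  An all-constant table returns F = 0, P = 1 rather than 0/0.
  Repeated-measures/mixed models are out of scope.
- **Summaries** are mean (SEM) per group × period cell; SEM is undefined at
  n = 1 (warning).  The heat-map table pivots band-peak Power to fields of
  view (ordered by animal, then field) × periods, with missing cells as NaN.

## Problem sizes in tests and the acceptance script

Closed-loop tests run on reduced geometries chosen as the package's own
test sizes: single capillaries of ~75 µm in 16–120 px frames, 6-s clips for
velocity recovery (two seeds per speed at 50/100/200/500 µm/s), 30.5-s
single-wavelength clips for flow classification (25 seeds × 4 programs in
the suite; 10 × 4 in the script), 120-s CWS records for period recovery
(20 seeds × 4 periods), 500 simulations for the ROUT rates, and full
5 × 8 × 3 spectroscopy cohorts for the end-to-end group comparison
(20 replicates in the suite, 5 in the script).  All randomness is seeded;
the acceptance script derives every child seed from its `--seed` argument.

## Known limitations

- The velocity estimator assumes a single dominant motion per window;
  windows mixing two populations (e.g. mid-reversal) return the dominant
  one.
- Tract SO₂ assumes the two cameras are co-registered; no registration is
  performed.
- The incident-intensity surface requires plasma gaps within each ~1-s
  block; a capillary packed wall-to-wall with cells would bias I₀ low.
- The in vivo 438/450 calibration constants and the lineal-density →
  hematocrit conversion are placeholders; absolute SO₂ and Hct values from
  real data require instrument calibration.
- Classification of real recordings inherits the 0-assignment convention:
  velocities below 10 µm/s without tract displacement are treated as
  stopped.
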