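# Methods

This note documents the models implemented in `ribbonflux`, the
numerical choices behind them, what the synthetic-data generators do and
do not emulate, and the design decisions taken where the procedure was
genuinely open.

## Correlation analysis

### Estimators

`correlation.autocorrelate` implements the normalised fluctuation
autocorrelation g(τ) = ⟨δF(t)δF(t+τ)⟩/⟨F⟩² with δF = F − ⟨F⟩, where the
mean is taken over the full trace and the product average over the
(n − k) overlapping sample pairs at integer lag k. The zero-baseline
convention is used throughout (an uncorrelated trace gives g = 0); the
"plus-one" convention appears only when a model curve is rendered in its
literal printed form (below). Cross-correlation normalises by the
product of the two channel means.

Two lag schemes are provided. `direct` evaluates every integer lag up to
`max_lag`. `multiple-tau` keeps the quasi-logarithmic lag grid of a
hardware multiple-tau correlator — m = 16 linear lags, then m/2 lags per
level with spacing doubling each level — but evaluates every retained
lag with the exact estimator rather than correlating block-averaged
(rebinned) signals. Per-level signal rebinning in hardware correlators
is a throughput optimisation that biases long-lag values by the local
curvature of g; computing a few hundred exact lags is cheap in software,
and the scheme then agrees with the direct estimator to machine
precision at shared lags, which the test suite asserts at 1e-8 relative
on traces of 10^4 samples.

Standard errors, when requested, come from splitting the trace into 5
contiguous blocks, correlating each, and taking the standard error of
the block estimates. These SEs carry only 4 degrees of freedom and are
used for error bars and sanity checks; model fits weight uniformly by
default because block SEs at long lags are themselves noisy and
empirically degrade τ_D estimates.

### Diffusion model

The fitted model is the 3D Gaussian-volume form

g(τ) = b + (1 + T/(1−T)·e^(−τ/τ_T)) · (γ/N) · (1+(τ/τ_D)^a)^(−1) · (1+(τ/τ_D)^a/s²)^(−1/2)

with s = z/r₀ the axial-to-lateral aspect ratio and a an
anomalous-diffusion exponent applied to the reduced lag (a = 1: normal
diffusion). Printed renderings of this model in the literature sometimes
carry the axial factor to the power −1 with a trailing +1 and no
explicit baseline; `model_g(..., as_printed=True)` reproduces that
literal form (and tags the curve "plus-one") so both variants are
available and tested, while the default is the standard form with a free
additive baseline b.

The baseline term matters in practice: a finite trace of length
T_total has E[ĝ(τ)] ≈ g(τ) − (2/T_total)∫g, an approximately constant
negative offset (~5% of the amplitude at T_total = 100 τ_D). Fitting
with b free absorbs this bias; fixing b = 0 pulls τ_D down by tens of
percent on 200-s traces of a 2-s species. Slow-species fits therefore
float N, τ_D and b and fix the shape parameters (T = 0, a = 1, s from
the known beam geometry, γ = 1).

The shape factor γ defaults to 1, i.e. it is folded into the apparent
molecule number; 2^(−3/2) is selectable. N is defined so that
g(0⁺) = γ/N exactly when the number in the effective volume
V_eff = π^(3/2) r₀² z is N — the convention under which the generator's
`n_mean` and the fitted N coincide, and under which γ cancels from every
ratio used downstream. Amplitudes are always read from the fitted model,
never from the noisy first lag bin.

Two-component fits replace the diffusion factor with
Y·g_d(τ_D1) + (1−Y)·g_d(τ_D2), with τ_D1 < τ_D2 normalised by
construction (a parameter set supplied in the other order is flipped,
Y → 1−Y).

### Diffusion coefficient and bound numbers

`diffusion_coefficient` implements D = r₀²/(factor·τ_D) with factor 4
(the standard lateral relation) as default and 2 selectable;
`beam_radius_from_d` inverts it, which is how the beam radius is
calibrated from a species of known D and τ_D.

`n_bound` implements N_bound = N_g(N_r + Q·N_g)/N_cc − Q·N_g with
N_cc = 1/g_cc(0⁺), the reciprocal-amplitude convention that makes the
Q = 0 limit reduce to the textbook g_cc(0) = N_bound/(N_g N_r). The
printed one-line form of this estimator is typographically ambiguous
about grouping; the reading adopted here is the one with that reduction
property, stated as this package's choice rather than asserted as the
original authors' intent. Q is the green-into-red crosstalk ratio
(red-channel counts per molecule under green excitation over those under
red excitation). A negative estimate — possible when crosstalk is
overcorrected on noisy amplitudes — is clipped to zero and flagged.
Both bound fractions, N_bound/N_g and N_bound/N_r, are reported, since
co-movement percentages can be quoted against either channel.

## FCS/FCCS trace simulation

`synthetic.simulate_fcs_trace` runs Brownian dynamics of point emitters
in a periodic box: per step, Gaussian displacements of variance 2·D·dt
per axis; re-entry is periodic (teleport to the opposite face), which
keeps concentration exactly constant and is the standard choice for FCS
simulation. The detection weight is W(r) = exp(−2(x²+y²)/r₀² − 2z²/z_ax²);
each species contributes round(c·V_box) particles at concentration
c = n_mean/V_eff, so the realised `n_eff` (recorded in the ground truth)
differs from `n_mean` only by particle rounding. Photon counts per bin
are Poisson around the deterministic molecular rate plus background; the
red channel receives its own molecular signal plus Q times the green
molecular rate. Triplet blinking is a two-state telegraph process per
molecule with stationary dark fraction T and relaxation time τ_T.

Default study conditions, chosen once for desk scale: beam r₀ = 0.2 µm,
z = 1.0 µm; box half-widths 3× the beam radii (the detection weight at
the nearest face is e^(−18), so truncation is negligible); bin width
5 ms and 200 s duration for slow species (τ_D ≈ 2 s), 50 µs and 2 s for
fast ones (instrument hardware bins at sub-µs, but the correlation shape
at lags ≫ dt is unaffected by coarser binning and runtimes stay in
seconds); molecular brightness 25 counts/bin for slow-species runs
(= 5 kHz per molecule, a typical EGFP count rate — much dimmer settings
would add avoidable shot noise to the correlation estimates).

A single 200-s acquisition of a 2-s species contains only ~100
residence times, so its fitted τ_D scatters by ~±30%. The
`protocols` module therefore mirrors instrument practice: repeated
acquisitions (10 for diffusion-time measurements, 20 for FCCS, akin to
pooling cells/terminals) are simulated with sub-seeds derived from one
protocol seed, their correlation curves averaged, and the averaged curve
fitted. Under these conditions τ_D is recovered to ~5–15% and a planted
bound number of 3 molecules to better than 10%.

What the generator does not emulate: photobleaching, detector
afterpulsing and dead time, laser power fluctuations, membrane geometry
(diffusion is free 3D), and vesicle-to-vesicle brightness variation.
Passing tests therefore validate the estimator and fitting chain, not
robustness to these instrument artifacts.

## FRAP

`normalize_frap` maps a raw trace to f = (raw − raw[bleach_end])/(plateau
− raw[bleach_end]) with time rebased to zero at bleach end. The plateau
("maximum value of fluorescence") is estimated as the mean of the final
10% of post-bleach samples rather than the single largest sample, for
robustness to shot noise; on a noise-free, still-rising recovery this
leaves the last samples within a fraction of a percent of 1 rather than
exactly 1. A flat or decaying post-bleach trace has no dynamic range and
is rejected.

`fit_frap` fits f(t) = m·(1 − e^(−t/τ)). Because max-normalisation
forces the plateau toward 1, the mobile fraction is meaningful relative
to total pre-bleach signal only when a pre-bleach reference level is
supplied (then `mobile_vs_prebleach` = m divided by the normalised
pre-bleach level); otherwise m is reported relative to the recovered
plateau. Both conventions are exposed since published mobile fractions
do not always state which was used. Population kinetics average
normalised traces across cells before fitting (`fit_frap_batch`), which
is also how the averaging-reduces-error property is tested.

## TIRF movie analysis

### Segmentation

The segmentation image is built from the stimulus window: each pixel's
response F(t) − F₀ (F₀ = baseline-window mean) is divided by that
pixel's own baseline temporal SD, the root-mean-square over the window
is taken, and the result is smoothed (Gaussian, σ = 1 px) and sharpened
with the negated 5-point Laplacian. Noise normalisation is what removes
the shot-noise variance step at the footprint rim — without it the rim
segments into spurious ROIs; the RMS projection responds to rises and
falls alike, so accumulation and loss regions are found by one pass. The
enhanced image is thresholded at median + 5×(1.4826·MAD), components use
8-connectivity, components under 4 pixels are dropped, and survivors are
relabelled 1..n in raster order of their first pixel so labelling is
deterministic. All of these are configurable.

### Traces, responders, classes

ΔF/F uses F₀ from the first `baseline_window` (default 20) frames,
which must precede stimulus onset, after subtracting a per-frame
background taken from a user-supplied mask or, by default, the darkest
decile of the baseline image. ROIs whose baseline is non-positive after
background subtraction are excluded and reported, never silently
dropped.

A ROI responds when any post-onset ΔF/F sample exceeds ±k×SD_baseline
with k = 4 by default; the SD is the average of per-ROI baseline SDs (a
per-ROI SD is selectable). The threshold is applied to raw traces;
optional smoothing is deliberately not default since the published
criterion does not state it. Classification looks at the signed
significant excursion within a 10-s window from stimulus onset:
positive → accumulation, negative → loss; a responder whose only
crossing lies outside the window is kept with class "none". Each event
records its first-crossing frame, peak ΔF/F, and a single-exponential
recovery time fitted from the trace peak onward (left unset if the fit
fails; the event is retained). The event position is the
intensity-weighted centre of mass of its ROI's mean response during the
window, signed by the response direction.

### Geometry

Ribbon puncta are detected by thresholding the ribbon channel
(MAD-based or absolute threshold) and taking intensity-weighted centres
of mass; the effective radius is √(area/π)·pixel size. Event-to-ribbon
distance is the Euclidean distance to the nearest punctum centre, ties
broken toward the lowest index. Distance histograms use fixed 0.1-µm
bins from zero — wide enough to be stable at realistic localisation
noise, narrow enough to resolve the 0.4 µm (fusion) vs 0.8 µm (clathrin
turnover) radial modes, which the acceptance tests require to land in
distinct modal bins. Pearson colocalisation is the sample correlation
over a pixel mask, rejecting constant images.

## Movie simulation

`simulate_tirf_movie` renders baseline + footprint + events + noise:
an elliptical footprint (plateau 100 counts over a 10-count surround) on
a 96×96 px field at 0.1 µm/px and 0.1 s/frame, with three static ribbon
puncta rendered into a separate ribbon-channel image. The pixel size is
not a measured value but a plausible default for high-NA EMCCD TIRF
imaging and is configurable. Planted events are isotropic Gaussian spots
(σ = 0.15 µm); the evanescent-field axial decay is collapsed into event
amplitude because the 2D pipeline never sees the axial dimension.
Event centres are drawn on rings around ribbon centres (radius ~
N(0.4, 0.05) µm for fusion, N(0.8, 0.05) µm for clathrin
accumulation/loss), rejected outside the footprint, and kept ≥ 0.5 µm
apart so that planted events map to distinct ROIs. Time courses: fusion
rises after a uniform onset within the stimulus and decays
double-exponentially (30% at 2.5 s, 70% at 13 s); clathrin events start
within one frame of stimulus onset, rise with τ = 0.5 s and decay with
τ = 15 s (configurable 10–20 s); loss events are the negative of the
accumulation course. Amplitudes are specified in multiples of the
expected per-pixel noise SD at the footprint plateau
(√(plateau + σ_read²)), default 8×. Noise is Poisson on the clean rate
plus Gaussian read noise (σ = 2). Default movies span 25 s (30 baseline
frames, then stimulus + ≥20 s of recovery, enforced at validation).

Not emulated: photobleaching, stage drift, uneven illumination, EMCCD
gain-register statistics, and diffuse (non-punctate) fusion signal.
Detection scores on these movies are therefore upper bounds on real-data
performance; the pipeline's robustness hooks for real data are the
configurable thresholds and the affine-invariance of ΔF/F.

## Decay fitting and condition comparison

`fit_decay` fits from the trace maximum (pre-peak samples are the
caller's responsibility to exclude; the function rejects traces not
starting at their peak). In `auto` mode the double-exponential is
accepted only when (i) an F-ratio test on residual sums of squares
rejects the single model at α = 0.05 and (ii) the double is
identifiable: each component carries ≥ 2% of the amplitude and the slow
time constant is below 10× the trace span. Without the identifiability
guard, noise on truly single-exponential data occasionally buys a
significant F with a vanishing-weight runaway component; with it, the
false-complexity rate is zero across the 20 seeded replicates in the
test suite while genuinely double data is still selected. A double fit
whose time constants agree within 5% collapses to the equivalent single
fit and is flagged. Fits of a decay are only attempted on ≥10 samples.

`compare_conditions` reports fold_change_tau = mean(treated τ)/mean
(control τ) and fold_change_event_count = control/treated counts; the
half-recovery time t½ (τ·ln 2 for a single exponential, numerically
inverted for a double) is available separately since a "~3-fold slowing"
can be quoted on either scale. Event counts are compared as raw totals;
per-terminal means are a caller-side division.

## Units, formats, reproducibility

Pixel coordinates are 0-based (row, col); physical coordinates are in
µm with origin at the image corner, x along columns; times in seconds.
CSV is UTF-8, comma-separated, header row, '.' decimal. Movies travel as
multi-page float32 TIFF with a JSON metadata sidecar. Every simulation
seed is an explicit config field (no global RNG state); protocol
sub-seeds derive deterministically from the protocol seed; identical
configs reproduce outputs bit-for-bit, which the I/O tests assert on
serialized tables. Pipeline runs record the seed, a SHA-256 config hash
and the package version in their JSON report.

## Problem sizes

Desk-scale defaults were chosen so the full test suite and analysis
scripts run on a single CPU in minutes: slow-species FCS pools 10–20
acquisitions of 200 s at 5-ms bins (~190 particles each), movies are
250×96×96 with 13 planted events, and the imaging acceptance checks
pool ten seeded movies. Larger boxes, finer bins or more repetitions
only tighten the statistics; the estimators themselves are size-agnostic.
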