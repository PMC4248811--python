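# ribbonflux

Quantitative analysis of clathrin and synaptic-vesicle dynamics at
ribbon synapses, built for three live-cell measurement modalities:

- **FCS / FCCS** — fluorescence (cross-)correlation spectroscopy of
  intensity traces recorded in a confocal detection volume, yielding
  diffusion times, molecule numbers and co-diffusing (bound) fractions;
- **FRAP** — fluorescence recovery after photobleaching of the
  TIRF-visible membrane footprint, yielding recovery time constants and
  mobile fractions;
- **TIRF movie analysis** — segmentation of stimulated terminal
  footprints into ROIs, ΔF/F extraction, threshold-crossing responder
  selection, accumulation/loss classification, and event-to-ribbon
  distance geometry around the active zone.

Because live-cell recordings of this kind are rarely shareable, the
package ships first-class synthetic-data generators (Brownian-dynamics
photon traces, noisy recovery curves, TIRF movies with planted,
ground-truthed events) so that every pipeline stage is testable end to
end. It targets cell biologists and microscopists who need a scriptable,
reproducible version of this analysis chain, and methods developers who
want a ground-truthed sandbox for detection and fitting algorithms.

## Models

Autocorrelation of a trace F(t) uses the zero-baseline convention

    g(τ) = ⟨δF(t)·δF(t+τ)⟩ / ⟨F⟩²,   δF(t) = F(t) − ⟨F⟩

fitted with the 3D Gaussian-volume diffusion model (optional triplet
blinking with fraction T and time τ_T, anomalous exponent a, aspect
ratio s = z/r₀):

    g(τ) = b + (1 + T/(1−T)·e^(−τ/τ_T)) · (γ/N)
           · (1 + (τ/τ_D)^a)^(−1) · (1 + (τ/τ_D)^a / s²)^(−1/2)

with a two-component variant Y·g_d(τ_D1) + (1−Y)·g_d(τ_D2). The
diffusion coefficient follows from D = r₀²/(4·τ_D). Dual-colour
cross-correlation g_cc(τ) = ⟨δP₁·δP₂(t+τ)⟩/(⟨P₁⟩⟨P₂⟩) gives the bound
molecule number with spectral-crosstalk ratio Q:

    N_bound = N_g·(N_r + Q·N_g)/N_cc − Q·N_g,   N_cc = 1/g_cc(0⁺)

FRAP recoveries are fitted with f(t) = m·(1 − e^(−t/τ)); response
decays with A·e^(−t/τ) or A·(p·e^(−t/τ_fast) + (1−p)·e^(−t/τ_slow)),
with an F-ratio test deciding when the second component is warranted.

## Worked example

```python
from ribbonflux import correlation as corr
from ribbonflux import frap, pipeline, synthetic

# beam radius calibrated from the vesicle marker, applied to clathrin
r0 = corr.beam_radius_from_d(0.005, tau_d=4.61)
d = corr.diffusion_coefficient(tau_d=2.3, r0=r0)
print(f"beam radius r0 = {r0:.3f} um -> D_clathrin = {d:.4f} um^2/s")

# noisy FRAP trace with known ground truth, fitted end to end
trace = synthetic.simulate_frap_trace(tau=7.1, mobile_fraction=0.6,
                                      noise_sigma=0.02, seed=3)
fit = frap.fit_frap(trace)
print(f"FRAP: tau = {fit.tau:.2f} s, mobile fraction = "
      f"{fit.mobile_fraction:.2f}")

# one synthetic movie through the full imaging pipeline
movie, ribbons, truth = synthetic.simulate_tirf_movie(
    synthetic.MovieSimConfig(seed=7))
events, rois, traces = pipeline.run_tirf_pipeline(movie, ribbons)
match = pipeline.match_events(events, truth)
print(f"movie: {match.n_detected} detections / {match.n_true} planted, "
      f"{match.n_class_correct} classes correct")
```

prints

```
beam radius r0 = 0.304 um -> D_clathrin = 0.0100 um^2/s
FRAP: tau = 7.11 s, mobile fraction = 0.60
movie: 13 detections / 13 planted, 13 classes correct
```

The first line calibrates the squared beam radius from a synaptic-vesicle
marker (D = 0.005 µm²/s at residence time 4.61 s) and converts the
clathrin residence time of 2.3 s into its diffusion coefficient — the
two proteins move alike, consistent with clathrin riding on
vesicle-scale carriers rather than diffusing freely. The second line
shows the recovery fit returning the generator's τ = 7.1 s and 60%
mobile fraction from a 2%-noise trace. The third runs
segment → extract → detect → classify → distance on a simulated movie
with 13 planted events (6 fusion hotspots ~0.4 µm from ribbon centres,
4 clathrin-accumulation and 3 clathrin-loss regions ~0.8 µm out) and
recovers all of them with correct classes.

## Analysis scripts

The `analysis/` directory holds numbered narrative drivers that exercise
the library at study scale and write their tables under `results/`:

| script | what it measures |
| --- | --- |
| `01_fcs_diffusion.py` | τ_D and D of two slow species from pooled simulated acquisitions |
| `02_fccs_binding.py` | bound number and bound fractions of a co-diffusing mixture, with and without crosstalk |
| `03_frap_recovery.py` | recovery τ and mobile fraction from averaged noisy traces |
| `04_tirf_events.py` | detection scores, event kinetics and ribbon-distance histograms over ten movies |
| `05_inhibitor_comparison.py` | fold-changes in recovery τ and event counts, control vs inhibitor-like condition |

A command-line interface mirrors the library
(`ribbonflux simulate|fcs|frap|events|geometry|kinetics|run`); see
`ribbonflux --help`.

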