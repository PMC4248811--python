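"""Measurement protocols: repeated simulated acquisitions, pooled fits.

A single FCS acquisition of a slowly diffusing species carries large
statistical uncertainty (a 200 s trace holds only ~100 diffusion times),
so — as on the instrument, where runs are repeated and several cells are
pooled — these protocols simulate ``n_reps`` independent acquisitions,
average the correlation curves, and fit the averaged curve.  All
sub-seeds derive deterministically from the protocol seed.
"""

from __future__ import annotations

import numpy as np

from . import correlation as corr
from . import synthetic as syn

__all__ = ["SLOW_SPECIES_FIT_FIXED", "acquire_curves", "acquire_fccs_curves",
           "fcs_diffusion_protocol", "fccs_protocol"]

# one-component amplitude/time fits hold the shape factors fixed and float
# N, tau_d and the finite-trace baseline offset
SLOW_SPECIES_FIT_FIXED = ("T", "tau_t", "s_ratio", "a", "gamma")


def _sub_seed(seed: int, rep: int) -> int:
    return (seed * 1009 + 101 * rep + 17) % (2**31 - 1)


def acquire_curves(species: tuple[syn.SpeciesSpec, ...], n_reps: int,
                   seed: int, dt: float = 5e-3, duration: float = 200.0,
                   max_lag: float = 20.0, crosstalk_q: float = 0.0,
                   beam: syn.BeamGeometry | None = None,
                   which: str = "gg",
                   ) -> corr.CorrelationCurve:
    """Average a correlation curve over repeated simulated acquisitions.

    ``which`` selects the estimator: "gg"/"rr" autocorrelation of the
    green/red channel, "gr" the green-red cross-correlation.
    """
    beam = beam or syn.BeamGeometry()
    curves = []
    lags = None
    for rep in range(n_reps):
        cfg = syn.FcsSimConfig(species=species, beam=beam, dt=dt,
                               duration=duration, crosstalk_q=crosstalk_q,
                               seed=_sub_seed(seed, rep))
        g, r, _ = syn.simulate_fcs_trace(cfg)
        if which == "gg":
            cur = corr.autocorrelate(g, max_lag)
        elif which == "rr":
            cur = corr.autocorrelate(r, max_lag)
        elif which == "gr":
            cur = corr.crosscorrelate(g, r, max_lag)
        else:
            raise ValueError(f"unknown estimator selector {which!r}")
        curves.append(cur.g)
        lags = cur.lags
    g_mean = np.mean(curves, axis=0)
    se = (np.std(curves, axis=0, ddof=1) / np.sqrt(n_reps)
          if n_reps > 1 else None)
    return corr.CorrelationCurve(lags=lags, g=g_mean, se=se)


def acquire_fccs_curves(species: tuple[syn.SpeciesSpec, ...], n_reps: int,
                        seed: int, dt: float = 5e-3, duration: float = 200.0,
                        max_lag: float = 20.0, crosstalk_q: float = 0.0,
                        beam: syn.BeamGeometry | None = None,
                        ) -> tuple[corr.CorrelationCurve, corr.CorrelationCurve,
                                   corr.CorrelationCurve]:
    """Pool both autocorrelations and the cross-correlation over repeated
    dual-channel acquisitions (all three estimators share each trace pair)."""
    beam = beam or syn.BeamGeometry()
    gg, rr, gr = [], [], []
    lags = None
    for rep in range(n_reps):
        cfg = syn.FcsSimConfig(species=species, beam=beam, dt=dt,
                               duration=duration, crosstalk_q=crosstalk_q,
                               seed=_sub_seed(seed, rep))
        g, r, _ = syn.simulate_fcs_trace(cfg)
        gg.append(corr.autocorrelate(g, max_lag).g)
        rr.append(corr.autocorrelate(r, max_lag).g)
        cur = corr.crosscorrelate(g, r, max_lag)
        gr.append(cur.g)
        lags = cur.lags

    def pool(stack):
        se = (np.std(stack, axis=0, ddof=1) / np.sqrt(n_reps)
              if n_reps > 1 else None)
        return corr.CorrelationCurve(lags=lags, g=np.mean(stack, axis=0),
                                     se=se)

    return pool(gg), pool(rr), pool(gr)


def fcs_diffusion_protocol(d_true: float, n_mean: float = 5.0,
                           brightness: float = 25.0, n_reps: int = 10,
                           seed: int = 0, dt: float = 5e-3,
                           duration: float = 200.0, max_lag: float = 20.0,
                           ) -> tuple[corr.DiffusionModelParams, float]:
    """Measure the diffusion time of one slow species.

    Returns the pooled-curve fit and the implied diffusion coefficient
    from D = r0^2 / (4 tau_d).
    """
    beam = syn.BeamGeometry()
    species = (syn.SpeciesSpec(n_mean=n_mean, D=d_true,
                               brightness_g=brightness),)
    curve = acquire_curves(species, n_reps, seed, dt=dt, duration=duration,
                           max_lag=max_lag, beam=beam)
    tau_guess = beam.r0**2 / (4 * d_true)
    fit = corr.fit_correlation(
        curve,
        init=corr.DiffusionModelParams(N=n_mean, tau_d=tau_guess / 2,
                                       s_ratio=beam.z / beam.r0),
        fixed=SLOW_SPECIES_FIT_FIXED)
    d_est = corr.diffusion_coefficient(fit.tau_d, beam.r0)
    return fit, d_est


def fccs_protocol(n_green_only: float = 3.0, n_red_only: float = 2.0,
                  n_bound_true: float = 3.0, d_true: float = 0.005,
                  brightness: float = 25.0, n_reps: int = 20, seed: int = 0,
                  crosstalk_q: float = 0.0, dt: float = 5e-3,
                  duration: float = 200.0, max_lag: float = 20.0,
                  ) -> corr.FccsResult:
    """Dual-colour bound-number measurement on a co-diffusing mixture.

    Simulates green-only, red-only and dual-labelled species, pools the
    three correlation curves over ``n_reps`` acquisitions, reads the
    apparent numbers off the fitted amplitudes and applies the
    crosstalk-corrected bound-number estimate.
    """
    beam = syn.BeamGeometry()
    species = (
        syn.SpeciesSpec(n_mean=n_green_only, D=d_true,
                        brightness_g=brightness),
        syn.SpeciesSpec(n_mean=n_red_only, D=d_true,
                        brightness_r=brightness),
        syn.SpeciesSpec(n_mean=n_bound_true, D=d_true,
                        brightness_g=brightness, brightness_r=brightness),
    )
    tau_guess = beam.r0**2 / (4 * d_true)
    cur_gg, cur_rr, cur_gr = acquire_fccs_curves(
        species, n_reps, seed, dt=dt, duration=duration, max_lag=max_lag,
        crosstalk_q=crosstalk_q, beam=beam)

    def amp_fit(curve, n0):
        return corr.fit_correlation(
            curve,
            init=corr.DiffusionModelParams(N=n0, tau_d=tau_guess,
                                           s_ratio=beam.z / beam.r0),
            fixed=SLOW_SPECIES_FIT_FIXED).N

    n_g = amp_fit(cur_gg, n_green_only + n_bound_true)
    n_r = amp_fit(cur_rr, n_red_only + n_bound_true)
    n_cc = amp_fit(cur_gr, (n_green_only + n_bound_true)
                   * (n_red_only + n_bound_true) / n_bound_true)
    return corr.n_bound(n_g, n_r, n_cc, q=crosstalk_q)
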