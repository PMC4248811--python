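"""Fluorescence correlation spectroscopy: correlators, diffusion models, fits.

This module computes auto- and cross-correlation curves from binned
intensity traces and fits the standard confocal-FCS diffusion models:

* single-component 3D diffusion through a Gaussian detection volume,
  optionally with a triplet (blinking) prefactor and an anomalous
  exponent ``a`` on the reduced lag,
* a two-component mixture of diffusion times (e.g. a slow vesicle-bound
  pool plus a fast free pool of clathrin),
* the dual-colour cross-correlation bound-number estimate with
  spectral-crosstalk correction.

Conventions
-----------
Correlation amplitudes use the *zero-baseline* convention
``g(tau) = <dF(t) dF(t+tau)> / <F>**2`` so that an uncorrelated trace
gives g = 0 and the zero-lag limit of the model equals ``gamma/N``
(plus an explicit additive ``baseline`` term if fitted).  Apparent
molecule numbers are reciprocal fitted amplitudes; the shape factor
``gamma`` defaults to 1 (folded into N) and cancels from all ratios
used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import lmfit
import numpy as np

__all__ = [
    "IntensityTrace",
    "CorrelationCurve",
    "DiffusionModelParams",
    "FccsResult",
    "autocorrelate",
    "crosscorrelate",
    "multiple_tau_lags",
    "model_g",
    "fit_correlation",
    "diffusion_coefficient",
    "beam_radius_from_d",
    "n_bound",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class IntensityTrace:
    """A uniformly binned fluorescence / photon-count time series.

    Parameters
    ----------
    values : array-like
        Counts (or arbitrary intensity units) per bin.
    dt : float
        Bin width in seconds.
    channel : str
        Free-form channel label ("green", "red", ...).
    """

    values: np.ndarray
    dt: float
    channel: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("trace must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace contains non-finite values")
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "values", v)

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class CorrelationCurve:
    """Correlation amplitudes on a grid of lag times.

    ``offset_convention`` records whether g decays to 0 ("zero-baseline",
    the library default) or to 1 ("plus-one", the printed-equation form).
    """

    lags: np.ndarray
    g: np.ndarray
    se: np.ndarray | None = None
    offset_convention: Literal["zero-baseline", "plus-one"] = "zero-baseline"

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if lags.shape != g.shape or lags.ndim != 1:
            raise ValueError("lags and g must be 1-D arrays of equal length")
        if lags.size and np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(g)):
            raise ValueError("correlation amplitudes must be finite")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "g", g)
        if self.se is not None:
            se = np.asarray(self.se, dtype=float)
            if se.shape != lags.shape:
                raise ValueError("se must match lags in shape")
            object.__setattr__(self, "se", se)


@dataclass
class DiffusionModelParams:
    """Parameters of the confocal diffusion autocorrelation model.

    ``N`` is the apparent molecule number (amplitude = gamma/N), ``tau_d``
    the diffusion (residence) time in seconds, ``T``/``tau_t`` the triplet
    fraction and its correlation time, ``s_ratio`` the axial-to-lateral
    aspect ratio z/r0 of the detection volume, ``a`` an anomalous-diffusion
    exponent on the reduced lag (1 = normal diffusion), ``gamma`` the
    geometric shape factor and ``baseline`` an additive offset.

    For a two-component fit set ``two_component=(Y, tau_d1, tau_d2)`` with
    fraction ``Y`` of the first (by convention faster... the *slow* pool in
    the clathrin use-case is listed first; ordering tau_d1 < tau_d2 is
    normalised on construction).
    """

    N: float = 1.0
    tau_d: float = 1.0
    T: float = 0.0
    tau_t: float | None = None
    s_ratio: float = 5.0
    a: float = 1.0
    gamma: float = 1.0
    baseline: float = 0.0
    two_component: tuple[float, float, float] | None = None
    stderr: dict[str, float] = field(default_factory=dict)
    redchi: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be > 0")
        if self.tau_d <= 0:
            raise ValueError("tau_d must be > 0")
        if not (0 <= self.T < 1):
            raise ValueError("triplet fraction T must lie in [0, 1)")
        if self.T > 0 and (self.tau_t is None or self.tau_t <= 0):
            raise ValueError("T > 0 requires a positive tau_t")
        if self.s_ratio <= 0 or self.a <= 0 or self.gamma <= 0:
            raise ValueError("s_ratio, a and gamma must be > 0")
        if self.two_component is not None:
            y, t1, t2 = self.two_component
            if not (0 <= y <= 1):
                raise ValueError("two-component fraction Y must lie in [0, 1]")
            if t1 <= 0 or t2 <= 0:
                raise ValueError("component diffusion times must be > 0")
            if t1 > t2:  # normalise ordering tau_d1 < tau_d2
                self.two_component = (1.0 - y, t2, t1)


@dataclass(frozen=True)
class FccsResult:
    """Bound-species numbers and fractions from dual-colour FCCS amplitudes."""

    n_g: float
    n_r: float
    n_cc: float
    q: float
    n_bound: float
    frac_green_bound: float
    frac_red_bound: float
    clipped: bool = False


# ---------------------------------------------------------------------------
# correlators
#
# The "direct" scheme evaluates every integer lag up to max_lag with the
# textbook estimator.  The "multiple-tau" scheme keeps the quasi-logarithmic
# lag grid of a hardware multiple-tau correlator (m lags per level, lag
# spacing doubling each level) but evaluates each retained lag exactly, so
# the two schemes agree to machine precision at shared lags; the classic
# per-level signal rebinning is a throughput trick that would bias long
# lags by the curvature of g and is deliberately not used.


def _check_trace_pair(a: IntensityTrace, b: IntensityTrace) -> None:
    if a.values.size != b.values.size:
        raise ValueError("traces must have equal length")
    if not np.isclose(a.dt, b.dt):
        raise ValueError("traces must share the same bin width dt")


def _lag_indices(n: int, dt: float, max_lag: float,
                 scheme: str, m: int) -> np.ndarray:
    max_k = int(np.floor(max_lag / dt))
    max_k = min(max_k, n - 2)
    if max_k < 1:
        raise ValueError("max_lag shorter than one bin")
    if scheme == "direct":
        return np.arange(1, max_k + 1)
    if scheme != "multiple-tau":
        raise ValueError(f"unknown correlator scheme {scheme!r}")
    ks: list[int] = list(range(1, min(m, max_k) + 1))
    spacing = 1
    while ks[-1] < max_k:
        spacing *= 2
        start = ks[-1] + spacing
        level = np.arange(start, min(start + spacing * (m // 2), max_k + 1),
                          spacing)
        if level.size == 0:
            break
        ks.extend(int(k) for k in level)
    return np.asarray(ks, dtype=int)


def _raw_correlation(x: np.ndarray, y: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """<dx(t) dy(t+k)> at each integer lag k (full-trace means removed)."""
    dx = x - x.mean()
    dy = y - y.mean()
    out = np.empty(ks.size)
    for i, k in enumerate(ks):
        out[i] = np.dot(dx[:-k], dy[k:]) / (dx.size - k)
    return out


def _block_se(x: np.ndarray, y: np.ndarray, ks: np.ndarray, norm: float,
              n_blocks: int = 5) -> np.ndarray | None:
    """Standard errors from correlating >=5 contiguous trace segments."""
    n = x.size
    seg = n // n_blocks
    if seg <= ks.max() + 1:
        return None
    est = []
    for b in range(n_blocks):
        xs, ys = x[b * seg:(b + 1) * seg], y[b * seg:(b + 1) * seg]
        if xs.mean() == 0 or ys.mean() == 0:
            return None
        est.append(_raw_correlation(xs, ys, ks) / norm)
    return np.std(est, axis=0, ddof=1) / np.sqrt(n_blocks)


def autocorrelate(trace: IntensityTrace, max_lag: float,
                  scheme: Literal["direct", "multiple-tau"] = "multiple-tau",
                  m: int = 16, with_se: bool = False) -> CorrelationCurve:
    """Normalised fluorescence autocorrelation g(tau) = <dF dF_tau>/<F>^2.

    Parameters
    ----------
    max_lag : float
        Largest lag (s); must be below half the trace duration.
    scheme : {"direct", "multiple-tau"}
        Linear lag grid, or quasi-logarithmic grid with ``m`` lags per
        doubling level.
    with_se : bool
        Attach standard errors estimated by splitting the trace into 5
        contiguous blocks.
    """
    if max_lag >= trace.duration / 2:
        raise ValueError("max_lag must be < trace duration / 2")
    mean = trace.mean
    if mean == 0:
        raise ValueError("zero-mean trace: cannot normalise by <F>^2")
    ks = _lag_indices(trace.values.size, trace.dt, max_lag, scheme, m)
    g = _raw_correlation(trace.values, trace.values, ks) / mean**2
    se = _block_se(trace.values, trace.values, ks, mean**2) if with_se else None
    return CorrelationCurve(lags=ks * trace.dt, g=g, se=se)


def crosscorrelate(trace1: IntensityTrace, trace2: IntensityTrace,
                   max_lag: float,
                   scheme: Literal["direct", "multiple-tau"] = "multiple-tau",
                   m: int = 16, with_se: bool = False) -> CorrelationCurve:
    """Cross-correlation g_cc(tau) = <dP1(t) dP2(t+tau)> / (<P1><P2>)."""
    _check_trace_pair(trace1, trace2)
    if max_lag >= trace1.duration / 2:
        raise ValueError("max_lag must be < trace duration / 2")
    m1, m2 = trace1.mean, trace2.mean
    if m1 == 0 or m2 == 0:
        raise ValueError("zero-mean trace: cannot normalise by <P1><P2>")
    ks = _lag_indices(trace1.values.size, trace1.dt, max_lag, scheme, m)
    g = _raw_correlation(trace1.values, trace2.values, ks) / (m1 * m2)
    se = (_block_se(trace1.values, trace2.values, ks, m1 * m2)
          if with_se else None)
    return CorrelationCurve(lags=ks * trace1.dt, g=g, se=se)


def multiple_tau_lags(n: int, dt: float, max_lag: float, m: int = 16) -> np.ndarray:
    """The quasi-logarithmic lag grid (in seconds) used by the correlator."""
    return _lag_indices(n, dt, max_lag, "multiple-tau", m) * dt


# ---------------------------------------------------------------------------
# diffusion models


def _diff_component(tau: np.ndarray, tau_d: float, a: float,
                    s_ratio: float, as_printed: bool) -> np.ndarray:
    lateral = 1.0 / (1.0 + (tau / tau_d) ** a)
    axial = 1.0 + (tau / tau_d) ** a / s_ratio**2
    if as_printed:
        return lateral / axial
    return lateral / np.sqrt(axial)


def model_g(params: DiffusionModelParams, lags: Iterable[float],
            as_printed: bool = False) -> CorrelationCurve:
    """Evaluate the diffusion autocorrelation model on a lag grid.

    Default form (zero-baseline convention, plus an explicit ``baseline``)::

        g(tau) = baseline + (1 + T/(1-T) e^(-tau/tau_t)) * gamma/N
                 * (1 + (tau/tau_d)^a)^-1
                 * (1 + (r0/z)^2 (tau/tau_d)^a)^-1/2

    With ``as_printed=True`` the axial factor enters to the power −1 and a
    trailing +1 replaces the fitted baseline, reproducing the literal
    printed rendering of the equations (the curve is then tagged with the
    "plus-one" offset convention).  A two-component parameter set replaces
    the diffusion factor by ``Y*diff(tau_d1) + (1-Y)*diff(tau_d2)``.
    """
    tau = np.asarray(list(lags) if not isinstance(lags, np.ndarray) else lags,
                     dtype=float)
    if np.any(tau < 0):
        raise ValueError("lags must be non-negative")
    if params.two_component is not None:
        y, t1, t2 = params.two_component
        diff = (y * _diff_component(tau, t1, params.a, params.s_ratio, as_printed)
                + (1 - y) * _diff_component(tau, t2, params.a, params.s_ratio,
                                            as_printed))
    else:
        diff = _diff_component(tau, params.tau_d, params.a, params.s_ratio,
                               as_printed)
    triplet = 1.0
    if params.T > 0:
        triplet = 1.0 + params.T / (1.0 - params.T) * np.exp(-tau / params.tau_t)
    g = triplet * (params.gamma / params.N) * diff
    if as_printed:
        return CorrelationCurve(lags=tau, g=g + 1.0,
                                offset_convention="plus-one")
    return CorrelationCurve(lags=tau, g=g + params.baseline)


def _model_eval(tau, N, tau_d, T, tau_t, s_ratio, a, gamma, baseline,
                Y=None, tau_d1=None, tau_d2=None):
    two = (Y, tau_d1, tau_d2) if Y is not None else None
    p = DiffusionModelParams(N=N, tau_d=tau_d, T=T,
                             tau_t=tau_t if T > 0 else None,
                             s_ratio=s_ratio, a=a, gamma=gamma,
                             baseline=baseline, two_component=two)
    return model_g(p, tau).g


def fit_correlation(curve: CorrelationCurve,
                    model_spec: Literal["one_component", "two_component"] = "one_component",
                    init: DiffusionModelParams | None = None,
                    fixed: Sequence[str] = ("T", "tau_t", "s_ratio", "a",
                                            "gamma", "baseline"),
                    use_se_weights: bool = False) -> DiffusionModelParams:
    """Weighted least-squares fit of the diffusion model to a curve.

    ``fixed`` names parameters held at their ``init`` values; everything
    else is free within its physical bounds.  Non-convergence is flagged on
    the result (``converged=False``), never silent.
    """
    init = init or DiffusionModelParams()
    nfree_max = curve.lags.size // 2
    p = lmfit.Parameters()
    p.add("N", value=init.N, min=1e-12)
    p.add("T", value=init.T, min=0.0, max=0.999)
    p.add("tau_t", value=init.tau_t or 1e-6, min=1e-12)
    p.add("s_ratio", value=init.s_ratio, min=1e-6)
    p.add("a", value=init.a, min=1e-6)
    p.add("gamma", value=init.gamma, min=1e-12)
    p.add("baseline", value=init.baseline)
    if model_spec == "two_component":
        y0, t1, t2 = init.two_component or (0.5, init.tau_d / 10, init.tau_d)
        p.add("tau_d", value=init.tau_d, min=1e-12, vary=False)
        p.add("Y", value=y0, min=0.0, max=1.0)
        p.add("tau_d1", value=t1, min=1e-12)
        p.add("tau_d2", value=t2, min=1e-12)
    else:
        p.add("tau_d", value=init.tau_d, min=1e-12)
    for name in fixed:
        if name in p:
            p[name].set(vary=False)
    if sum(par.vary for par in p.values()) > nfree_max:
        raise ValueError("need at least 2x more lag points than free parameters")

    weights = None
    if use_se_weights and curve.se is not None:
        se = np.where(curve.se > 0, curve.se, np.inf)
        weights = 1.0 / se

    def resid(pars):
        v = pars.valuesdict()
        kw = {}
        if model_spec == "two_component":
            kw = dict(Y=v["Y"], tau_d1=v["tau_d1"], tau_d2=v["tau_d2"])
        r = _model_eval(curve.lags, v["N"], v["tau_d"], v["T"], v["tau_t"],
                        v["s_ratio"], v["a"], v["gamma"], v["baseline"],
                        **kw) - curve.g
        return r * weights if weights is not None else r

    out = lmfit.minimize(resid, p, method="leastsq")
    v = out.params.valuesdict()
    two = None
    if model_spec == "two_component":
        two = (v["Y"], v["tau_d1"], v["tau_d2"])
    stderr = {k: par.stderr for k, par in out.params.items()
              if par.vary and par.stderr is not None}
    result = DiffusionModelParams(
        N=v["N"], tau_d=v["tau_d"], T=v["T"],
        tau_t=v["tau_t"] if v["T"] > 0 else None,
        s_ratio=v["s_ratio"], a=v["a"], gamma=v["gamma"],
        baseline=v["baseline"], two_component=two,
        stderr=stderr, redchi=out.redchi, converged=bool(out.success))
    return result


# ---------------------------------------------------------------------------
# derived quantities


def diffusion_coefficient(tau_d: float, r0: float,
                          geometry_factor: Literal[4, 2] = 4) -> float:
    """Diffusion coefficient D = r0^2 / (factor * tau_d) in um^2/s.

    ``geometry_factor=4`` is the standard 2D/confocal lateral relation;
    2 is selectable for the 1D convention.
    """
    if tau_d <= 0 or r0 <= 0:
        raise ValueError("tau_d and r0 must be positive")
    if geometry_factor not in (4, 2):
        raise ValueError("geometry_factor must be 4 or 2")
    return r0**2 / (geometry_factor * tau_d)


def beam_radius_from_d(d: float, tau_d: float,
                       geometry_factor: Literal[4, 2] = 4) -> float:
    """Invert D = r0^2/(factor*tau_d) for the beam radius r0 (um)."""
    if d <= 0 or tau_d <= 0:
        raise ValueError("d and tau_d must be positive")
    return float(np.sqrt(geometry_factor * d * tau_d))


def n_bound(n_g: float, n_r: float, n_cc: float, q: float = 0.0) -> FccsResult:
    """Co-diffusing (bound) molecule number from FCCS amplitudes.

    ``n_g``/``n_r`` are reciprocal autocorrelation amplitudes of the two
    channels, ``n_cc`` the reciprocal cross-correlation amplitude, ``q``
    the green-into-red spectral crosstalk ratio.  The estimate is::

        n_bound = n_g * (n_r + q * n_g) / n_cc - q * n_g

    which at q=0 reduces to the textbook g_cc(0) = N_bound/(N_g N_r).
    A negative estimate (crosstalk overcorrection) is clipped to zero and
    flagged.
    """
    if n_g <= 0 or n_r <= 0 or n_cc <= 0:
        raise ValueError("channel and cross numbers must be positive")
    if q < 0:
        raise ValueError("crosstalk q must be >= 0")
    nb = n_g * (n_r + q * n_g) / n_cc - q * n_g
    clipped = nb < 0
    nb = max(nb, 0.0)
    return FccsResult(
        n_g=n_g, n_r=n_r, n_cc=n_cc, q=q, n_bound=nb,
        frac_green_bound=float(np.clip(nb / n_g, 0.0, 1.0)),
        frac_red_bound=float(np.clip(nb / n_r, 0.0, 1.0)),
        clipped=bool(clipped))
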