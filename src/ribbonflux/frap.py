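"""Fluorescence recovery after photobleaching: normalisation and fitting.

Recovery of fluorescence into a bleached membrane footprint is summarised
by a single-exponential model ``f(t) = mobile * (1 - exp(-t/tau))`` where
``tau`` is the recovery time constant and ``mobile`` the mobile fraction.
Traces are normalised to 0 at the post-bleach minimum and 1 at the
post-bleach plateau; if a pre-bleach reference level is supplied the
mobile fraction is additionally reported relative to total pre-bleach
signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

__all__ = ["FrapTrace", "FrapFit", "normalize_frap", "fit_frap", "fit_frap_batch"]


@dataclass(frozen=True)
class FrapTrace:
    """Normalised recovery trace; t in seconds since bleach end, t[0] = 0."""

    t: np.ndarray
    f: np.ndarray
    prebleach_reference: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        f = np.asarray(self.f, dtype=float)
        if t.shape != f.shape or t.ndim != 1 or t.size < 2:
            raise ValueError("t and f must be matching 1-D arrays (n >= 2)")
        if t[0] != 0:
            raise ValueError("time axis must start at 0 (bleach end)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time axis must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "f", f)


@dataclass(frozen=True)
class FrapFit:
    """Fitted recovery parameters.

    ``mobile_fraction`` is relative to the normalisation reference: the
    recovered plateau when no pre-bleach level is known, otherwise the
    pre-bleach signal (``mobile_vs_prebleach``).
    """

    tau: float
    mobile_fraction: float
    se_tau: float | None
    se_mobile: float | None
    converged: bool
    mobile_vs_prebleach: float | None = None


def normalize_frap(raw, bleach_end_index: int, dt: float = 1.0,
                   prebleach_index: int | None = None,
                   plateau_fraction: float = 0.1) -> FrapTrace:
    """Normalise a raw bleach-recovery trace.

    ``f = (raw - raw[bleach_end]) / (plateau - raw[bleach_end])`` with the
    plateau estimated as the mean of the final ``plateau_fraction`` of
    post-bleach samples (robust to single-sample shot noise); time is
    rebased to 0 at ``bleach_end_index``.  If ``prebleach_index`` is given,
    the mean raw signal up to that index is stored as a reference so the
    mobile fraction can be expressed relative to total pre-bleach signal.
    """
    raw = np.asarray(raw, dtype=float)
    if not (0 <= bleach_end_index < raw.size - 1):
        raise ValueError("bleach_end_index out of range")
    post = raw[bleach_end_index:]
    f0 = post[0]
    k = max(1, int(np.ceil(plateau_fraction * post.size)))
    plateau = post[-k:].mean()
    if plateau <= f0:
        raise ValueError("flat or decaying post-bleach trace: zero dynamic range")
    f = (post - f0) / (plateau - f0)
    ref = None
    if prebleach_index is not None:
        pre = raw[:prebleach_index + 1].mean()
        ref = (pre - f0) / (plateau - f0)
    t = np.arange(post.size) * dt
    return FrapTrace(t=t, f=f, prebleach_reference=ref)


def fit_frap(trace: FrapTrace) -> FrapFit:
    """Least-squares fit of mobile*(1 - exp(-t/tau)) to a recovery trace."""
    if trace.t.size < 10:
        raise ValueError("need at least 10 samples for a recovery fit")
    p = lmfit.Parameters()
    span = trace.t[-1]
    p.add("mobile", value=float(np.clip(trace.f[-5:].mean(), 0.05, 1.0)),
          min=0.0, max=1.5)
    p.add("tau", value=span / 5, min=1e-9)

    def resid(pars):
        v = pars.valuesdict()
        return v["mobile"] * (1 - np.exp(-trace.t / v["tau"])) - trace.f

    out = lmfit.minimize(resid, p, method="leastsq")
    v = out.params.valuesdict()
    mobile = float(np.clip(v["mobile"], 0.0, 1.0))
    vs_pre = None
    if trace.prebleach_reference is not None and trace.prebleach_reference > 0:
        vs_pre = float(np.clip(mobile / trace.prebleach_reference, 0.0, 1.0))
    return FrapFit(tau=v["tau"], mobile_fraction=mobile,
                   se_tau=out.params["tau"].stderr,
                   se_mobile=out.params["mobile"].stderr,
                   converged=bool(out.success),
                   mobile_vs_prebleach=vs_pre)


def fit_frap_batch(traces: list[FrapTrace]) -> tuple[FrapFit, FrapTrace]:
    """Average normalised traces across cells, then fit the average.

    All traces must share a time base.  Returns the fit and the averaged
    trace (population kinetics are fitted on the mean, matching how
    per-cell recovery curves are pooled before the exponential fit).
    """
    if not traces:
        raise ValueError("no traces supplied")
    t0 = traces[0].t
    for tr in traces[1:]:
        if tr.t.shape != t0.shape or not np.allclose(tr.t, t0):
            raise ValueError("all traces must share the same time base")
    f = np.mean([tr.f for tr in traces], axis=0)
    refs = [tr.prebleach_reference for tr in traces]
    ref = float(np.mean([r for r in refs if r is not None])) \
        if any(r is not None for r in refs) else None
    avg = FrapTrace(t=t0, f=f, prebleach_reference=ref)
    return fit_frap(avg), avg
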