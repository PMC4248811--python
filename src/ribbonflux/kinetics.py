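"""Exponential decay kinetics and condition comparisons.

Fluorescence decays after a stimulus (sypHy decline on endocytosis,
clathrin loss from accumulation sites) are fitted from their peak with a
single exponential ``A exp(-t/tau)`` or a double exponential
``A (p exp(-t/tau_fast) + (1-p) exp(-t/tau_slow))``.  ``auto`` model
selection accepts the extra two parameters only when an F-ratio test on
the residual sum of squares is significant at alpha = 0.05.  Conditions
(e.g. control vs the clathrin inhibitor Pitstop2) are compared through
fold-changes of mean recovery time and of event counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import lmfit
import numpy as np
from scipy import stats

__all__ = ["DecayFit", "ConditionComparison", "fit_decay", "compare_conditions",
           "half_recovery_time"]


@dataclass(frozen=True)
class DecayFit:
    """Fitted decay parameters; ``tau_fast < tau_slow`` is enforced."""

    model: Literal["single", "double"]
    amplitude: float
    tau: float | None = None
    fraction_fast: float | None = None
    tau_fast: float | None = None
    tau_slow: float | None = None
    residual_norm: float = np.nan
    converged: bool = True
    collapsed_to_single: bool = False

    def __post_init__(self) -> None:
        if self.model == "single":
            if self.tau is None or self.tau <= 0:
                raise ValueError("single model requires tau > 0")
        else:
            if self.tau_fast is None or self.tau_slow is None:
                raise ValueError("double model requires both taus")
            if self.tau_fast <= 0 or self.tau_slow <= 0:
                raise ValueError("taus must be positive")
            if self.tau_fast > self.tau_slow:
                raise ValueError("tau_fast must be <= tau_slow")
            if not (0 <= self.fraction_fast <= 1):
                raise ValueError("fraction_fast must lie in [0, 1]")

    @property
    def mean_tau(self) -> float:
        """Amplitude-weighted mean time constant."""
        if self.model == "single":
            return float(self.tau)
        return float(self.fraction_fast * self.tau_fast
                     + (1 - self.fraction_fast) * self.tau_slow)


@dataclass(frozen=True)
class ConditionComparison:
    fold_change_tau: float
    fold_change_event_count: float
    n_control: int
    n_treated: int
    control_mean_tau: float | None = None
    treated_mean_tau: float | None = None


def _fit_single(t: np.ndarray, y: np.ndarray) -> tuple[dict, float, bool]:
    p = lmfit.Parameters()
    p.add("A", value=float(y[0]) if y[0] != 0 else 1.0)
    p.add("tau", value=float(t[-1] / 5) or 1.0, min=1e-12)

    def resid(pars):
        v = pars.valuesdict()
        return v["A"] * np.exp(-t / v["tau"]) - y

    out = lmfit.minimize(resid, p, method="leastsq")
    v = out.params.valuesdict()
    return v, float(np.sum(out.residual**2)), bool(out.success)


def _fit_double(t: np.ndarray, y: np.ndarray) -> tuple[dict, float, bool]:
    p = lmfit.Parameters()
    p.add("A", value=float(y[0]) if y[0] != 0 else 1.0)
    p.add("p", value=0.5, min=0.0, max=1.0)
    p.add("tau_fast", value=float(t[-1] / 20) or 0.1, min=1e-12)
    p.add("tau_slow", value=float(t[-1] / 2) or 1.0, min=1e-12)

    def resid(pars):
        v = pars.valuesdict()
        return (v["A"] * (v["p"] * np.exp(-t / v["tau_fast"])
                          + (1 - v["p"]) * np.exp(-t / v["tau_slow"])) - y)

    out = lmfit.minimize(resid, p, method="leastsq")
    v = out.params.valuesdict()
    if v["tau_fast"] > v["tau_slow"]:
        v["tau_fast"], v["tau_slow"] = v["tau_slow"], v["tau_fast"]
        v["p"] = 1.0 - v["p"]
    return v, float(np.sum(out.residual**2)), bool(out.success)


def fit_decay(trace: Sequence[float], dt: float,
              model: Literal["single", "double", "auto"] = "auto",
              alpha: float = 0.05,
              collapse_rel_tol: float = 0.05) -> DecayFit:
    """Fit an exponential decay to a trace that starts at its maximum.

    ``auto`` fits both models and keeps the double only if the F-ratio
    test on residual sums of squares rejects the single at ``alpha`` *and*
    the double is identifiable: each component carries >= 2% of the
    amplitude and the slow time constant is resolvable within 10x the
    trace span.  A double fit whose two time constants are within
    ``collapse_rel_tol`` relative is collapsed to the equivalent single
    fit and flagged.
    """
    y = np.asarray(trace, dtype=float)
    if y.ndim != 1 or y.size < 10:
        raise ValueError("decay trace must be 1-D with >= 10 points")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if np.argmax(y) != 0:
        raise ValueError("trace must start at its maximum (fit from the peak)")
    t = np.arange(y.size) * dt

    if model == "single":
        v, rss, ok = _fit_single(t, y)
        return DecayFit(model="single", amplitude=v["A"], tau=v["tau"],
                        residual_norm=np.sqrt(rss), converged=ok)

    vd, rss_d, ok_d = _fit_double(t, y)
    # collapse when the two components are indistinguishable or one
    # carries negligible amplitude / an unresolvable time constant
    collapse = (abs(vd["tau_slow"] - vd["tau_fast"])
                <= collapse_rel_tol * vd["tau_slow"]
                or not (0.02 <= vd["p"] <= 0.98)
                or vd["tau_slow"] > 10 * t[-1])
    if model == "auto" or collapse:
        vs, rss_s, ok_s = _fit_single(t, y)
        if collapse:
            return DecayFit(model="single", amplitude=vs["A"], tau=vs["tau"],
                            residual_norm=np.sqrt(rss_s), converged=ok_s,
                            collapsed_to_single=True)
        if model == "auto":
            n, k_s, k_d = y.size, 2, 4
            identifiable = (0.02 <= vd["p"] <= 0.98
                            and vd["tau_slow"] <= 10 * t[-1])
            if rss_d <= 0 or rss_s <= rss_d * (1 + 1e-12):
                use_double = rss_d > 0 and rss_s > rss_d
            else:
                f = ((rss_s - rss_d) / (k_d - k_s)) / (rss_d / (n - k_d))
                pval = stats.f.sf(f, k_d - k_s, n - k_d)
                use_double = pval < alpha
            use_double = use_double and identifiable
            if not use_double:
                return DecayFit(model="single", amplitude=vs["A"],
                                tau=vs["tau"], residual_norm=np.sqrt(rss_s),
                                converged=ok_s)
    return DecayFit(model="double", amplitude=vd["A"],
                    fraction_fast=float(np.clip(vd["p"], 0, 1)),
                    tau_fast=vd["tau_fast"], tau_slow=vd["tau_slow"],
                    residual_norm=np.sqrt(rss_d), converged=ok_d)


def half_recovery_time(fit: DecayFit) -> float:
    """Time at which the fitted decay falls to half its amplitude."""
    if fit.model == "single":
        return float(fit.tau * np.log(2))
    t = np.linspace(0, 20 * fit.tau_slow, 20001)
    y = (fit.fraction_fast * np.exp(-t / fit.tau_fast)
         + (1 - fit.fraction_fast) * np.exp(-t / fit.tau_slow))
    return float(t[np.searchsorted(-y, -0.5)])


def compare_conditions(control_fits: Sequence[DecayFit], control_count: int,
                       treated_fits: Sequence[DecayFit], treated_count: int
                       ) -> ConditionComparison:
    """Fold-changes between conditions.

    ``fold_change_tau = mean(treated tau) / mean(control tau)`` (>1 means
    the treated decay is slower) and ``fold_change_event_count =
    control_count / treated_count`` (>1 means fewer events under
    treatment).
    """
    if control_count <= 0 or treated_count <= 0:
        raise ValueError("event counts must be positive")
    ct = [f.mean_tau for f in control_fits]
    tt = [f.mean_tau for f in treated_fits]
    fold_tau = float(np.mean(tt) / np.mean(ct)) if ct and tt else np.nan
    return ConditionComparison(
        fold_change_tau=fold_tau,
        fold_change_event_count=control_count / treated_count,
        n_control=control_count, n_treated=treated_count,
        control_mean_tau=float(np.mean(ct)) if ct else None,
        treated_mean_tau=float(np.mean(tt)) if tt else None)
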