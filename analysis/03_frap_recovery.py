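"""FRAP recovery kinetics from averaged noisy traces.

Simulates seven bleach-recovery traces per condition (clathrin-like:
tau = 7.1 s, 60% mobile; vesicle-marker-like: tau = 8.1 s, 50% mobile;
2% Gaussian noise), averages the normalised traces as a pooled cell
population, and fits the single-exponential recovery.  Finding: both
time constants and mobile fractions are recovered to within a few
percent from the averaged traces.

Writes results/frap_recovery.csv.
"""

from pathlib import Path

import pandas as pd

from ribbonflux import frap
from ribbonflux.synthetic import simulate_frap_trace

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1
N_CELLS = 7

conditions = {
    "clathrin_like": dict(tau=7.1, mobile=0.60),
    "vesicle_marker": dict(tau=8.1, mobile=0.50),
}

rows = []
for name, p in conditions.items():
    traces = [simulate_frap_trace(p["tau"], p["mobile"], noise_sigma=0.02,
                                  dt=0.1, duration=40.0,
                                  seed=SEED * 1000 + i)
              for i in range(N_CELLS)]
    fit, _avg = frap.fit_frap_batch(traces)
    rows.append({
        "condition": name, "n_cells": N_CELLS,
        "tau_true_s": p["tau"], "tau_fit_s": fit.tau,
        "se_tau_s": fit.se_tau,
        "mobile_true": p["mobile"], "mobile_fit": fit.mobile_fraction,
        "mobile_vs_prebleach": fit.mobile_vs_prebleach,
        "converged": fit.converged,
    })
    print(f"{name}: tau {fit.tau:.2f} s (true {p['tau']}), "
          f"mobile {fit.mobile_fraction:.2f} (true {p['mobile']})")

OUT.mkdir(exist_ok=True)
pd.DataFrame(rows).to_csv(OUT / "frap_recovery.csv", index=False)
print(f"\nwrote {OUT / 'frap_recovery.csv'}")
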