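"""Co-diffusion of two labels measured by simulated FCCS.

Simulates a dual-colour mixture — 3 green-only, 2 red-only and 3
dual-labelled molecules in the detection volume, all diffusing slowly —
pools 20 repeated acquisitions, reads apparent molecule numbers off the
fitted correlation amplitudes and applies the crosstalk-corrected
bound-number estimate.  Finding: the planted bound number (3) is
recovered within a few percent, and the implied bound fractions
(3/6 = 50% of green, 3/5 = 60% of red) match the ground truth; a second
run with 10% green-into-red crosstalk shows the correction restoring the
same answer.

Writes results/fccs_binding.csv.
"""

import time
from pathlib import Path

import pandas as pd

from ribbonflux import protocols as pr

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1

rows = []
for label, q in (("no_crosstalk", 0.0), ("crosstalk_10pc", 0.1)):
    t0 = time.time()
    res = pr.fccs_protocol(n_green_only=3.0, n_red_only=2.0,
                           n_bound_true=3.0, crosstalk_q=q, seed=SEED)
    rows.append({
        "condition": label,
        "crosstalk_q": q,
        "n_g_fit": res.n_g, "n_r_fit": res.n_r, "n_cc_fit": res.n_cc,
        "n_bound_fit": res.n_bound, "n_bound_true": 3.0,
        "frac_green_bound": res.frac_green_bound,
        "frac_red_bound": res.frac_red_bound,
        "clipped": res.clipped,
    })
    print(f"{label}: n_bound {res.n_bound:.2f} (true 3.0); "
          f"bound fractions green {res.frac_green_bound:.2f} "
          f"(true 0.50), red {res.frac_red_bound:.2f} (true 0.60); "
          f"{time.time() - t0:.0f} s compute")

OUT.mkdir(exist_ok=True)
pd.DataFrame(rows).to_csv(OUT / "fccs_binding.csv", index=False)
print(f"\nwrote {OUT / 'fccs_binding.csv'}")
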