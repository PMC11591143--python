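"""From raw LMD traces to methane phenotypes and LME/HME groups.

Simulates 60 cows x 3 sessions of laser-methane-detector readings, runs
the range filter -> peak threshold -> per-cow averaging -> population QC
chain, then selects low/high-emitting extreme groups at mean +/- 0.65 SD.
"""

import numpy as np
import pandas as pd

from ch4rumen import phenotyping as ph
from ch4rumen.simulate import TraceSimSpec, simulate_lmd_sessions

sessions, latent = simulate_lmd_sessions(TraceSimSpec(seed=1))
print(f"{len(sessions)} sessions of {len(sessions[0].readings)} readings each")

cows = ph.phenotype_cows(sessions)  # range filter 200-8000, mean+SD peaks, QC
rng = np.random.default_rng(2)
cows["milk_yield"] = rng.uniform(28, 42, len(cows)).round(1)
cows["parity"] = rng.integers(1, 3, len(cows))

selected = ph.select_groups(cows[cows["qc_pass"]])
for label in ("LME", "HME"):
    grp = selected.loc[selected["group"] == label, "phenotype"]
    s = ph.summarize_group(grp, label)
    print(f"{label}: n={s.n} mean={s.mean:.1f} sd={s.sd:.1f} CV={s.cv}% ppm x m")

lme = selected.loc[selected["group"] == "LME", "phenotype"]
hme = selected.loc[selected["group"] == "HME", "phenotype"]
t, df, p = ph.welch_compare(lme, hme)
print(f"Welch t-test LME vs HME: t={t:.2f}, df={df:.1f}, p={p:.2e}")
# The two extreme groups differ strongly by construction; CV ~ 10-20%
# within groups mirrors what field LMD campaigns report.
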