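"""Calibration of the synthetic generator and the vote-count filter:
DL coverage at the corpus-like effect structure, and the exact binomial
tail of the consensus filter."""
import numpy as np
from scipy import stats

from mirmeta import (SimulationConfig, effects_from_studies, pool,
                     simulate_prediction_matrix, simulate_studies,
                     vote_count_targets)

delta, covered, reps = 0.8, 0, 500
for rep in range(reps):
    cfg = SimulationConfig(k_studies=30, delta=delta, tau=0.2,
                           specimen_mix=0.0, n_case_range=(20, 100),
                           n_control_range=(20, 100), seed=30_000 + rep)
    _, studies = simulate_studies(cfg)
    res = pool(effects_from_studies(studies), model="random_dl")
    covered += res.ci_low <= delta <= res.ci_high
print(f"DL 95% CI coverage at delta=0.8, tau=0.2, k=30: "
      f"{covered / reps:.1%} over {reps} replicates")

m = simulate_prediction_matrix(10_000, vote_prob=0.5, seed=7)
frac = len(vote_count_targets(m, min_votes=8)) / 10_000
print(f">=8/12 consensus fraction at p=0.5: {frac:.3f} "
      f"(exact binomial tail {stats.binom.sf(7, 12, 0.5):.3f})")
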