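#!/usr/bin/env python
"""Force-based selection of post-skill-acquisition trials.

Emulates a 15-trial learning sequence by generating cohorts whose
force-tracking noise shrinks across trials (skill acquisition), then
selects the first consecutive triplet with the lowest force-target RMSE.
Writes results/trial_selection.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from mupool import preprocess, synthetic  # noqa: E402

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
N_TRIALS = 15


def main() -> None:
    rng = np.random.default_rng(SEED)
    summaries = []
    # learning curve: measurement/motor noise decays across trials, with a
    # noisy plateau after ~trial 10
    for k in range(N_TRIALS):
        skill = 1.0 / (1.0 + 0.5 * k)
        sim = synthetic.generate_cohort(
            n_trials=1,
            seed=int(rng.integers(2**31)),
            plateau_s=12.0,
            force_noise_sd=0.05 + 2.0 * skill,
        )
        tr = sim.cohort.trials[0]
        sl = sim.truth["plateau"]
        s = preprocess.force_rmse(
            tr.force[sl], tr.target[sl], tr.fs, trial_index=k + 1
        )
        summaries.append(s)
    sel = preprocess.select_post_skill_trials(summaries)
    df = pd.DataFrame(
        {
            "trial": [s.trial_index for s in summaries],
            "rmse": [s.rmse for s in summaries],
            "cov_force_pct": [s.cov_force for s in summaries],
            "selected": [
                s.trial_index in sel.selected_indices for s in summaries
            ],
        }
    )
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "trial_selection.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    print(f"\nselected post-skill trials: {sel.selected_indices}")


if __name__ == "__main__":
    main()
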