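"""Partition the mixed source signature into plant and non-plant pathways.

Inverts the three-component mixing model
delta13C_mix = deltaP*kp + deltaNP*(1-kp) + eps over 15-day windows
(first window opening 3 days after transplanting) using a process-model
k_p table, then forms the pathway-weighted source signature
delta13C_source = deltaP*kp + deltaNP*(1-kp).
"""

import numpy as np
import pandas as pd

from paddyiso.config import ScenarioConfig
from paddyiso.partition import combine_heights_and_models, partition_season
from paddyiso.synthetic import simulate_kp_tables, simulate_truth

cfg = ScenarioConfig(rng_seed=42)
truth = simulate_truth(cfg)

# daily mixed signature: truth source + contamination offset + 0.5 permil noise
rng = np.random.default_rng(0)
daily = pd.DataFrame(
    {
        "date": truth.date,
        "height_m": 0.5,
        "delta13c_mix_permil": truth.true_delta_source_permil
        + cfg.epsilon_truth_permil
        + rng.normal(0, 0.5, len(truth)),
    }
)
kp = simulate_kp_tables(truth, cfg)

windows = partition_season(daily, kp, truth.date.iloc[0], bootstrap_B=200, seed=0)
combined = combine_heights_and_models(windows)
ibis = combined[combined.model_label == "IBIS"]

print("window  deltaP  deltaNP  eps  source+-sd  [flag=kp nearly constant]")
for _, w in ibis.iterrows():
    print(
        f"{int(w.window_index):3d}  {w.deltaP_permil:8.2f} {w.deltaNP_permil:8.2f}"
        f" {w.epsilon_permil:5.2f} {w.delta_source_permil:8.2f}+-{w.sd_source:.2f}"
        f"  {'*' if w.identifiability_flag else ''}"
    )
print(
    "\nsource signatures are more negative than the raw window-mean mix by ~eps;"
    "\nflagged windows have too little k_p variation to separate the end-members"
    "\n(the box-bound midpoint is reported there)."
)
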