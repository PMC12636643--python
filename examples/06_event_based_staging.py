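"""Order pre-symptomatic biomarker events and stage subjects.

Generates staged cross-sectional z-score data (each subject sits at an
unknown stage of a hidden event sequence), fits the single-subtype
event-based model, and compares the recovered ordering and stages to the
planted truth.
"""

import pandas as pd
from scipy.stats import kendalltau, spearmanr

from csfprognostics.staging import EventModelConfig, fit_event_sequence
from csfprognostics.synthetic import SimConfig, generate_staging_data

sim = SimConfig(n_subjects=250, ebm_n_biomarkers=6, ebm_z=2.0,
                ebm_sigma=0.5, seed=6)
Z, truth = generate_staging_data(sim)

cfg = EventModelConfig(z_event=2.0, sigma=0.5, n_restarts=10,
                       mcmc_iters=3000, seed=1)
seq = fit_event_sequence(Z, cfg)

print("true order:      ", " -> ".join(truth.true_sequence))
print("recovered order: ", " -> ".join(seq.order))
pos_map = {b: i for i, b in enumerate(seq.order)}
pos_true = {b: i for i, b in enumerate(truth.true_sequence)}
tau = kendalltau([pos_true[b] for b in Z.columns],
                 [pos_map[b] for b in Z.columns]).statistic
rho = spearmanr(pd.Series(truth.true_stages)[seq.map_stages.index],
                seq.map_stages).statistic
print(f"Kendall tau(order): {tau:.2f}; Spearman rho(stages): {rho:.3f}")
print(f"MCMC acceptance rate: {seq.acceptance_rate:.2f}")
print("positional probability of the first event:")
print(seq.positional_probability.loc[seq.order[0]].round(3).to_string())
print("A concentrated first row means the earliest biomarker change is "
      "identified with little positional uncertainty.")
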