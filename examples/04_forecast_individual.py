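"""Roll out an individual multi-year forecast beyond the observed history.

After consuming a subject's observed visits, each predicted visit is fed
back as the next input with mask = 0 (the cell treats it as imputed) and
age incremented, producing an autoregressive trajectory. Printed: one
test subject's observed K-MMSE and CDR-SB series and the 3-year forecast
in normalized units. Multi-step forecasts compound the model's one-step
behaviour, so they drift toward the cohort's learned decline pattern.
"""

import numpy as np

from trajgru import SimulationConfig, simulate
from trajgru.network import rollout
from trajgru.training import TrainConfig, stratified_splits, train

truth = simulate(SimulationConfig(n_subjects=100, n_visits=4, p_miss=0.1, seed=2))
cohort = truth.observed
config = TrainConfig(seed=2, max_epochs=300, patience=25)
_, _, tr, va, te = next(iter(stratified_splits(cohort.labels, config, 2)))
fitted = train(cohort, config, tr, va)

prep = fitted.prepare(cohort.subset(te[:1]))
age_span = fitted.normalizer.maximum[cohort.schema.index("age")] - \
    fitted.normalizer.minimum[cohort.schema.index("age")]
fc = rollout(
    prep.x_core, prep.demo, prep.mask_core, prep.delta_core,
    fitted.params, horizon=3, age_step=1.0 / age_span,
)

sch = cohort.schema
core = sch.core_names
for name in ("kmmse", "cdr_sb"):
    ci = core.index(name)
    obs = prep.x_core[0, :, ci]
    pred = fc["pred_c"][0, :, sch.cognitive_names.index(name)]
    print(f"{name:7s} observed {np.round(obs, 3)}  forecast +1..+3y {np.round(pred, 3)}")
print("(normalized units; later steps feed on earlier predictions, mask = 0)")
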