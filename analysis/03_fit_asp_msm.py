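#!/usr/bin/env python
"""Full pipeline on the deprotonated ensemble with bootstrap uncertainty.

Runs featurize → normalize → tICA → K-means (12 states) → reversible MSM at
the 80 ns lag → four-macrostate lumping on the ASP fixture dataset, then 200
rounds of whole-trajectory bootstrap. The recovered populations should match
the generator: Src-like 52%, intermediate 40%, active 7%, DFG-out 1%.
"""

from pathlib import Path

import pandas as pd

from kinasemsm import pipeline as pl, synthetic as syn

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

asp, _ = syn.calibrate_btk_chains()
spec = syn.default_emission_spec(asp)
labels = syn.sample_discrete(asp, 5000, 100, seed=42)
trajs = syn.emit_features(labels, spec, seed=43, dt=asp.dt)

config = pl.PipelineConfig(
    tica_lag_ns=80.0, n_components=3, kinetic_mapping=True,
    n_clusters=12, cluster_seed=7, markov_lag_ns=80.0,
    n_bootstrap=200, bootstrap_seed=11)
result = pl.run_pipeline(config, trajs,
                         macro_feature_points=syn.macro_mean_points(asp, spec))
for line in result.log:
    print("  " + line)

boots = pl.bootstrap_pipeline(result)
rows = []
for macro, truth in asp.macro_populations().items():
    s = boots[f"population.{macro}"]
    rows.append({"macrostate": macro, "generator": truth, "median": s.median,
                 "lo95": s.lo95, "hi95": s.hi95,
                 "covered": s.lo95 <= truth <= s.hi95})
table = pd.DataFrame(rows)
table.to_csv(RESULTS / "asp_populations.csv", index=False)
print(table.round(4).to_string(index=False))
print(f"implied timescales (ns): {result.timescales_ns[:3].round(1).tolist()}")
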