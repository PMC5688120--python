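#!/usr/bin/env python
"""Sample synthetic ensembles and inspect the tICA spectrum.

Draws the standard fixture dataset (100 trajectories × 5,000 steps at 80 ns)
from the ASP chain, emits 50-dimensional Gaussian features (20 signal + 30
noise), and fits tICA at the 80 ns lag. The three leading eigenvalues should
track the chain's three nontrivial transition-matrix eigenvalues, deflated
by the emission signal-to-noise of each mode; everything below them is
intra-macrostate or distractor variance.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from kinasemsm import synthetic as syn, tica
from kinasemsm.features import normalize_features

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

asp, _ = syn.calibrate_btk_chains()
spec = syn.default_emission_spec(asp)
labels = syn.sample_discrete(asp, 5000, 100, seed=42)
trajs = syn.emit_features(labels, spec, seed=43, dt=asp.dt)

normed, _ = normalize_features(trajs)
model = tica.fit_tica(normed, lag_ns=80.0, n_components=3, kinetic_mapping=True)

chain_mu = np.sort(np.linalg.eigvals(asp.transition_matrix).real)[::-1]
table = pd.DataFrame({
    "tic": np.arange(1, 4),
    "tica_eigenvalue": model.eigenvalues[:3],
    "tica_timescale_ns": model.timescales()[:3],
    "chain_eigenvalue_same_rank": chain_mu[1:4],
})
table.to_csv(RESULTS / "tica_spectrum.csv", index=False)
print(table.round(4).to_string(index=False))
print("note: tICA eigenvalues sit below the chain eigenvalues by each mode's")
print("linear-readout SNR factor; ordering of the three exchange processes is preserved")
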