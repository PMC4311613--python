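"""PARAFAC on the emulated session: metric table -> tensor -> ALS.

Builds the (pair x stimulus x repetition) kappa_sync tensor from a
simulated session, centers it in all three modes, chooses the number
of components (scree + congruence rules) and reports how well the
fitted pair loadings match the planted assemblies.
"""

import numpy as np

import spikefac as sf

cfg = sf.ExperimentSimConfig()
ds = sf.simulate_experiment(cfg, seed=0)
table = sf.compute_metric_table(ds)
tensor = sf.center_tensor(sf.build_tensor(table))
print(f"tensor shape (pairs, stimuli, repetitions): {tensor.shape}")

report = sf.select_components(tensor, f_max=6, seed=0, n_starts=6)
print("\n F   explained var   max |congruence|")
for F, ev, cg in zip(report.candidates, report.explained_variance_pct,
                     report.max_congruence):
    mark = " <- chosen" if F == report.chosen else ""
    print(f" {F}      {ev:6.2f}%          {cg:.3f}{mark}")

model = report.models[report.chosen]
P = sf.planted_pair_loadings(cfg, sf.enumerate_pairs(ds.grid))
match = np.abs(sf.congruence_matrix(P, model.A)).max(axis=1)
print(f"\nplanted-assembly congruence of fitted pair loadings: "
      f"{np.round(match, 3)}")
print()
print("Selection stops where extra components stop reducing the "
      "residual (scree) or start duplicating each other (congruence); "
      "here it recovers the three planted assemblies, and each fitted "
      "pair-mode component matches one planted membership pattern.")
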