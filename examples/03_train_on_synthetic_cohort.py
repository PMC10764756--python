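"""Train the index end to end on a small synthetic cohort.

Generates 40 subjects whose theta-alpha peak frequency and beta
amplitude follow a latent cognition score on two electrodes, runs the
exhaustive (band, order, dimension) search with cross-validated
Spearman rho as the cost, and fits the final model. Prints the winning
configuration per electrode and the search score.
"""

import leapd

spec = leapd.CohortSpec(n_subjects=40, channels=("P8", "PO7"),
                        informative=("P8", "PO7"), duration=10.0, seed=7)
cohort = leapd.generate_cohort(spec)
pre = {sid: leapd.preprocess_recording(rec)
       for sid, rec in cohort.recordings.items()}

grid = leapd.GridSpec.default(step=8.0, min_width=8.0, orders=(3, 5, 7))
results = leapd.grid_search(pre, cohort.table, ["P8", "PO7"], grid,
                            folds=5, seed=7)
for entry in results:
    cfg = entry.config
    print(f"{entry.electrode}: band {cfg.band[0]:.0f}-{cfg.band[1]:.0f} Hz, "
          f"order K={cfg.order}, subspace dim n={cfg.dim}, "
          f"CV rho = {entry.rho:.3f}")

model = leapd.fit_model(pre, cohort.table, [e.config for e in results],
                        seed=7)
sid = cohort.table["id"].iloc[0]
res = model.score_recording(pre[sid])
score = cohort.table["MoCA"].iloc[0]
print(f"\nsubject {sid} (MoCA {score}): combined index = {res.combined:.3f}")
print("-> the search found configurations whose out-of-fold indices rank"
      " subjects consistently with the latent score (positive CV rho)")
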