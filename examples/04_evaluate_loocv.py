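"""Leave-one-out evaluation with a score-shuffled control.

Generates a 60-subject cohort, evaluates fixed electrode
configurations by LOOCV (subspaces refit without each held-out
subject), and repeats with randomly shuffled cognition scores. The
true-score run should show a strong rank correlation and AUC; the
shuffled run should collapse to chance, showing the pipeline does not
manufacture signal.
"""

import leapd

spec = leapd.CohortSpec(n_subjects=60, channels=("P8", "PO7"),
                        informative=("P8", "PO7"), duration=15.0, seed=3)
cohort = leapd.generate_cohort(spec)
pre = {sid: leapd.preprocess_recording(rec)
       for sid, rec in cohort.recordings.items()}
configs = [leapd.ElectrodeConfig(el, (2.0, 18.0), 3, 2)
           for el in ("P8", "PO7")]

loo = leapd.loocv(pre, cohort.table, configs)
null = leapd.randomization_test(pre, cohort.table, configs, seed=99)

for name, rep in [("true scores", loo), ("shuffled scores", null)]:
    cls = rep.classification
    print(f"{name:15s} rho = {rep.rho:+.3f} (p = {rep.rho_p:.2g}), "
          f"AUC = {cls['auc']:.3f}, accuracy = {cls['accuracy_pct']:.1f}%, "
          f"linear R^2 = {rep.regression['linear']['r2']:.3f}")
print("-> real structure survives LOOCV; permuted scores sit at chance")
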