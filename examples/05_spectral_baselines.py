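"""Traditional spectral comparators on a synthetic cohort.

Computes canonical band powers, the alpha/theta log ratio, and an
age-adjusted correlation topography for a cohort whose beta amplitude
tracks the latent score on two of four electrodes. The informative
electrodes should carry the significant beta-power correlations.
"""

import pandas as pd

import leapd

spec = leapd.CohortSpec(n_subjects=50, channels=("P8", "PO7", "Fz", "Cz"),
                        informative=("P8", "PO7"), duration=10.0,
                        ta_slope=0.0, ta_base=10.0, seed=12)
cohort = leapd.generate_cohort(spec)
pre = {sid: leapd.preprocess_recording(rec)
       for sid, rec in cohort.recordings.items()}

sid = cohort.table["id"].iloc[0]
x = pre[sid].channel("P8")
print(f"subject {sid}, electrode P8:")
for name, band in leapd.CANONICAL_BANDS.items():
    print(f"  {name:6s} ({band[0]:5.1f}-{band[1]:5.1f} Hz) "
          f"power = {leapd.band_power(x, spec.fs, band):.3e}")
print(f"  alpha/theta log10 ratio = "
      f"{leapd.alpha_theta_log_ratio(x, spec.fs):+.3f}")

beta = pd.DataFrame({
    el: [leapd.band_power(pre[s].channel(el), spec.fs, (13.0, 30.0))
         for s in cohort.table["id"]]
    for el in spec.channels})
topo = leapd.correlation_topography(
    beta, cohort.table["MoCA"].to_numpy(dtype=float),
    cohort.table["age"].to_numpy(dtype=float))
print("\nbeta-power correlation topography (age-adjusted partial rho):")
print(topo.round(3).to_string())
print("-> significance concentrates on the informative electrodes P8/PO7")
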