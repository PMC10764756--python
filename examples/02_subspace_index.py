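"""Score points by their distances to two group subspaces.

Builds two synthetic groups of LPC-coefficient vectors living near
different affine planes, fits one subspace per group, and prints the
normalized distance-ratio index rho for probes: rho near 0 means
impaired-like, near 1 normal-like, 0.5 equidistant.
"""

import numpy as np

import leapd

rng = np.random.default_rng(0)
K = 6  # LPC order = ambient dimension

impaired_pts = np.array([-1.0, 0, 0, 0, 0, 0]) + rng.standard_normal((20, K)) * 0.1
normal_pts = np.array([+1.0, 0, 0, 0, 0, 0]) + rng.standard_normal((20, K)) * 0.1

pair = leapd.SubspacePair(
    leapd.fit_affine_subspace(impaired_pts, n=2),
    leapd.fit_affine_subspace(normal_pts, n=2))

for label, probe in [
    ("impaired-group centroid", impaired_pts.mean(axis=0)),
    ("normal-group centroid", normal_pts.mean(axis=0)),
    ("midpoint between groups", np.zeros(K)),
    ("fresh impaired-like point", np.array([-1.0, 0.05, 0, 0, 0, 0])),
]:
    rho = leapd.leapd_index(probe, pair)
    verdict = "impaired" if rho < 0.5 else "normal"
    print(f"{label:28s} rho = {rho:.3f}  -> classified {verdict}")

combined = leapd.combine_indices([0.2, 0.4])
print(f"\ngeometric mean of per-electrode indices [0.2, 0.4] = {combined:.3f}")
print("-> the combined index stays within the per-electrode range")
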