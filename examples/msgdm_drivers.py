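"""Rank environmental drivers of turnover with multi-site GDM.

Simulates a community whose presence probabilities track altitude, fits
the I-spline dissimilarity model over 30 combination rounds at zeta
orders 2 and 10, and partitions the explained variance between
environment and geographic distance.
"""

import zetacomm as zc

ds = zc.generate_dataset(zc.SimulationConfig(
    seed=4, niche_strength=1.0, niche_covariate="altitude",
    occupancy_model="geometric"))
plots = ds.truth["presence_plot"]
cfg = zc.SchemeConfig(scheme="ALL", sam=1000, seed=0)

for order in (2, 10):
    av = zc.average_rounds(plots, ds.metadata, order, cfg, n_rounds=30)
    top = av.amplitude_mean.drop("distance").sort_values(ascending=False)
    print(f"zeta order {order}: mean r2 = {av.r2_mean:.2f}")
    print("  top I-spline amplitudes (dissimilarity contribution):")
    for var, amp in top.head(3).items():
        print(f"    {var:24s} {amp:.3f}")

design = zc.combination_design(plots, ds.metadata, 2, cfg)
vp = zc.variance_partition(design)
print("\nvariance partition at order 2:")
for k, v in vp.as_series().items():
    print(f"  {k:12s} {100 * v:5.1f}%")
print("the planted driver (altitude) should carry the largest amplitude,")
print("and the environment fraction should dominate distance.")
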