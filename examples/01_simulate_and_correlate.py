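"""Simulate a small regional ensemble and trace its dynamic correlation.

Builds an 8-region synthetic ensemble of daily search/consultation indices
(one epidemic wave, mild regional heterogeneity, 0.5%-of-K observation
noise), cumulates each region's series, and computes the growing-prefix
absolute Pearson correlation between the two cumulative indices — the
descriptive statistic that motivates coupling the two behaviors in one
model.  The printed band shows how tightly the two behaviors co-move once
a few days of data have accumulated.
"""

import predseek as ps

ensemble = ps.generate_ensemble(
    ps.predation_preset(), n_regions=8, n_days=61, noise=ps.NoiseSpec(0.005, seed=1)
)
pairs = [ps.cumulate(s) for s in ensemble]
traces = [ps.dynamic_correlation(p.x1, p.x2, region_id=p.region_id) for p in pairs]
summary = ps.correlation_summary(traces)

print("dynamic correlation of cumulative search vs consultation, 8 regions")
print("window_end  mean|r|     sd")
for t in (3, 10, 20, 40, 61):
    row = summary[summary["window_end"] == t].iloc[0]
    print(f"{t:10d}  {row['mean']:.4f}  {row['sd']:.4f}")
print("\nA mean |r| near 1 with a shrinking band says the cumulative indices")
print("co-move almost perfectly once the wave is underway.")
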