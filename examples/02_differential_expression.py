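"""Negative-binomial Wald differential expression on a simulated study.

Filters unexpressed genes, normalises with median-of-ratios size factors,
estimates moderated NB dispersions, fits the per-gene two-group GLM and calls
DEGs at |log2FC| > 1 and BH-adjusted p < 0.05.
"""

import reversig as rv

counts, truth = rv.simulate_three_group_counts(
    G=1000, n_per_group=6, frac_de=0.3, lfc_sd=2.0,
    reversal_fraction=1.0, dispersion=0.2, seed=42,
)

counts = rv.filter_unexpressed(counts)
size_factors = rv.estimate_size_factors(counts)
dispersions = rv.estimate_dispersions(counts, size_factors, ["disease", "control"])
table = rv.fit_nb_wald(counts, size_factors, dispersions, ("disease", "control"))
degs = rv.call_degs(table, contrast="disease_vs_control")

print("size factors (first 4):", size_factors.round(3).tolist()[:4])
print(f"median dispersion estimate: {dispersions.median():.3f} (planted 0.2)")
print()
print("top 5 genes by Wald statistic:")
print(table.sort_values("wald", ascending=False).head(5).round(3))
print()
print(f"DEGs: {degs.n_up} up, {degs.n_down} down "
      f"(planted: {len(truth.de_up['disease_vs_control'])} up, "
      f"{len(truth.de_down['disease_vs_control'])} down; weak planted effects"
      " with |log2FC| < 1 are not expected to be called)")
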