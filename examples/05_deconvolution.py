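"""Ridge-regression cell-type deconvolution against a pseudobulk reference.

Aggregates a labelled synthetic single-cell matrix into per-type CPM
signatures, mixes bulk samples with known proportions, and recovers the
composition by closed-form ridge with negative-coefficient zeroing.
"""

import numpy as np

import reversig as rv

sc_counts, profiles = rv.simulate_reference(K=4, G=1500, cells_per_type=60, seed=21)
reference = rv.build_reference(sc_counts)
print(f"reference: {reference.signatures.shape[0]} genes x "
      f"{len(reference.cell_types)} cell types (CPM signatures)")

truth = {"control": [0.55, 0.25, 0.12, 0.08],
         "disease": [0.30, 0.25, 0.12, 0.33]}
bulk, _ = rv.simulate_bulk(profiles, truth, n_per_group=6,
                           lib_size=400_000, dispersion=0.2, seed=22)

result = rv.deconvolve_cohort(bulk, reference, lam="cv", mode="per-group", seed=23)
for group, planted in truth.items():
    est = (result[result["group"] == group]
           .set_index("cell_type")["proportion"]
           .loc[reference.cell_types].to_numpy())
    err = np.max(np.abs(est - np.asarray(planted)))
    print(f"\n{group}: estimated {np.round(est, 3).tolist()}")
    print(f"{' ' * len(group)}  planted   {planted}  (max abs error {err:.3f})")

print("\nEach row is a composition over cell types; the disease arm's shift")
print("toward the last type (e.g. infiltrating immune cells) is recovered.")
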