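"""Cluster a simulated cohort, label cell types, and tabulate composition.

Clusters come from Leiden community detection on a kNN graph in PCA space;
each cluster is labeled by the marker panel with the highest mean module
score (expression-matched controls), and the per-patient percentage of
each cell type is the composition table.
"""

import tmescope as tm

counts, truth = tm.simulate_sc(tm.ScSimConfig(n_patients=3, cells_per_patient=600, seed=1))
filtered, _ = tm.qc_filter(counts)
nm = tm.log_normalize(filtered)
emb = tm.embed(nm, n_hvg=800, n_pcs=30, k_neighbors=20, seed=1)
# tumor cells segregate by patient, so the resolution must be high enough
# to split each patient's tumor cells into their ETC and EMT programs
clusters = tm.cluster(emb, resolution=1.6, seed=1)
print(f"{clusters.nunique()} clusters over {len(clusters)} cells")

panel = {t: tm.GeneSet(t, g) for t, g in truth.markers.items()}
ann = tm.assign_labels(clusters, nm, panel, seed=1)
accuracy = (ann.labels == truth.cell_types.loc[ann.obs.index]).mean()
print(f"label accuracy vs planted truth: {accuracy:.3f}")

ct = tm.composition(ann)
print(tm.format_table(ct))
# Each row is one patient and sums to 100%; tumor fractions vary by
# patient while stromal types are shared, mirroring real PDAC cohorts.
print(tm.composition_summary(ct, tissue="primary").round(1))
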