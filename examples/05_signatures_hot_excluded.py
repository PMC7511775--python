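"""Immune signatures by Ward clustering; hot vs excluded classification.

Cases are clustered on z-scored log densities of the immune phenotypes
(one view per compartment).  Separately, each phenotype's pseudocounted
tumor:stroma ratio splits the cohort at its median into immunologically
hot (tumor-enriched) versus immune-excluded cases.
"""

from immunotopo import (SimParams, assign_phenotypes, build_feature_matrix,
                        call_markers, classify_hot_excluded,
                        cluster_signatures, compute_densities,
                        derive_thresholds, generate_cohort)

cohort = generate_cohort(SimParams(n_cases=16, cores_per_case=2, seed=13))
cells = cohort.cells[cohort.cells["panel"] == "P1"].copy()
thr = derive_thresholds(cells, "P1", seed=6)
cells["label"] = assign_phenotypes(call_markers(cells, thr), "P1")
dens = compute_densities(cells, cohort.geometry)

matrix, dropped = build_feature_matrix(dens, "total", min_prevalence=0.05)
print(f"feature matrix: {matrix.shape[0]} cases x {matrix.shape[1]} "
      f"phenotypes (dropped: {dropped or 'none'})")

labels = cluster_signatures(matrix, 4)
print("cluster sizes (1 = largest):")
print(labels.value_counts().sort_index().to_string())

high = cohort.case_truth.set_index("case_id")["high_infiltration"]
print("\nhigh-infiltration fraction per cluster:")
for c, grp in labels.groupby(labels):
    frac = high.reindex(grp.index).mean()
    print(f"  cluster {c}: {frac:.2f}")

hot = classify_hot_excluded(dens, "NKp46_NKT", pseudocount=0.1)
print(f"\nNKp46+ NKT hot/excluded: {(hot['label'] == 'hot').sum()} hot, "
      f"{(hot['label'] == 'excluded').sum()} excluded "
      f"(median ratio {hot['ratio'].median():.2f})")
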