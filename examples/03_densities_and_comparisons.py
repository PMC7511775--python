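"""Compartment-normalized densities and rank-test comparisons.

Densities pool counts and areas across a case's cores (ratio of sums, not
mean of per-core ratios).  Tumor-versus-stroma contrasts use the exact
Wilcoxon signed-rank test; morphology contrasts use Mann-Whitney U.
"""

from immunotopo import (SimParams, assign_phenotypes, call_markers,
                        compute_densities, derive_thresholds,
                        generate_cohort, mann_whitney_u,
                        wilcoxon_signed_rank)

cohort = generate_cohort(SimParams(n_cases=12, cores_per_case=2, seed=5))
cells = cohort.cells[cohort.cells["panel"] == "P1"].copy()
thr = derive_thresholds(cells, "P1", seed=2)
cells["label"] = assign_phenotypes(call_markers(cells, thr), "P1")

dens = compute_densities(cells, cohort.geometry)

for phenotype in ("T_cell", "CD68_macrophage", "NKp46_NKT", "NK"):
    sub = dens[dens["phenotype"] == phenotype]
    wide = sub.pivot_table(index="case_id", columns="compartment",
                           values="density")
    res = wilcoxon_signed_rank(wide["tumor"], wide["stroma"])
    print(f"{phenotype:>18}: median tumor {wide['tumor'].median():8.1f}"
          f"  stroma {wide['stroma'].median():8.1f} cells/mm²"
          f"  (signed-rank p = {res.p:.4f}, {res.method})")

# morphology contrast on total T-cell density
total = dens[(dens["phenotype"] == "T_cell")
             & (dens["compartment"] == "total")].set_index("case_id")
morph = cohort.clinical.set_index("case_id")["morphology"]
gi = total.loc[morph[morph == "I-type"].index.intersection(total.index),
               "density"]
gp = total.loc[morph[morph == "PB-type"].index.intersection(total.index),
               "density"]
res = mann_whitney_u(gi, gp)
print(f"\nT-cell total density, I-type (n={len(gi)}) vs PB-type "
      f"(n={len(gp)}): U = {res.statistic:.0f}, p = {res.p:.4f}")
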