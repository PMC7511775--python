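"""Nearest-neighbor distances and 15 μm interaction-zone counts.

Distances never cross cores; self-matches are excluded by cell identity,
so coincident but distinct cells still interact.  Per-case summaries pool
cells across cores (each cell weighs equally, not each core).
"""

from immunotopo import (SimParams, assign_phenotypes, call_markers,
                        derive_thresholds, generate_cohort,
                        per_case_interaction_summary,
                        per_case_nearest_summary)

cohort = generate_cohort(SimParams(n_cases=10, cores_per_case=2, seed=9))
cells = cohort.cells[cohort.cells["panel"] == "P1"].copy()
thr = derive_thresholds(cells, "P1", seed=4)
cells["label"] = assign_phenotypes(call_markers(cells, thr), "P1")

print("mean distance from each cancer cell to the nearest immune cell:")
for target in ("T_cell", "CD68_macrophage", "NKp46_NKT", "NK"):
    out = per_case_nearest_summary(cells, "cancer", target)
    v = out["value"].dropna()
    print(f"  cancer -> {target:>16}: {v.mean():7.1f} μm "
          f"(across {len(v)} cases)")

print("\nmean cell count inside the 15 μm interaction zone:")
for ref in ("NKp46_NKT", "CD68_macrophage"):
    for neighbor in ("cancer", "T_cell"):
        out = per_case_interaction_summary(cells, ref, neighbor, radius=15.0)
        v = out["value"].dropna()
        print(f"  {ref:>16} ~ {neighbor:<10}: {v.mean():6.3f} cells")
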