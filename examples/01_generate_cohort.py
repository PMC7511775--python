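"""Generate a synthetic TMA cohort with known ground truth.

The generator emulates the structure of a two-panel multiplexed-IF tissue
microarray study: 1 mm cores with tumor nests in a stromal background,
per-class Poisson cell placement, bimodal log-normal marker intensities,
clinical covariates and Weibull proportional-hazards survival times.
"""

from immunotopo import SimParams, generate_cohort

params = SimParams(n_cases=10, cores_per_case=2, seed=7)
cohort = generate_cohort(params)

print(f"cases:            {cohort.clinical['case_id'].nunique()}")
print(f"cores:            {len(cohort.geometry)}"
      f" ({(cohort.geometry['tissue_type'] == 'benign').sum()} benign)")
print(f"cells (panel 1):  {(cohort.cells['panel'] == 'P1').sum()}")
print(f"cells (panel 2):  {(cohort.cells['panel'] == 'P2').sum()}")

areas = cohort.geometry[["tumor_area_mm2", "stroma_area_mm2"]].sum()
print(f"total tumor area:  {areas['tumor_area_mm2']:.2f} mm²")
print(f"total stroma area: {areas['stroma_area_mm2']:.2f} mm²")

truth = cohort.cell_truth[cohort.cell_truth["panel"] == "P1"]
print("\ntrue class counts (panel 1):")
print(truth["true_label"].value_counts().to_string())

events = cohort.clinical["event"].sum()
print(f"\ndeaths within follow-up: {events}/{len(cohort.clinical)}")
print(f"latent high-infiltration cases: "
      f"{cohort.case_truth['high_infiltration'].sum()}")
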