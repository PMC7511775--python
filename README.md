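# immunotopo

Spatial immunophenotyping pipeline for two-panel multiplexed-
immunofluorescence tissue-microarray (TMA) data, with a synthetic-data
generator carrying known ground truth.

Innate immune cells — NK cells, NKT subsets, macrophages, dendritic cells
and granulocytes — are not spread uniformly through a tumor: their density
differs between the malignant epithelium and the surrounding stroma, and
their proximity to cancer cells carries prognostic information. This
package implements the downstream analysis for that kind of study:

1. **Phenotype gating** — per-marker thresholds learned by a two-component
   Gaussian mixture on log intensity, then a combinatorial priority cascade
   assigns each cell one phenotype (e.g. CD3−CD56+NKp46+ → NK;
   CK+ → cancer; panel-2 DC gates exclude CD68+ macrophages).
2. **Compartment densities** — cells/mm² per case × phenotype ×
   compartment, pooling counts and areas across a case's cores; exact
   Wilcoxon signed-rank and Mann-Whitney tests for tumor-vs-stroma and
   morphology contrasts.
3. **Spatial statistics** — nearest-neighbor distances and 15 μm
   interaction-zone counts on the cell point pattern, never crossing core
   boundaries, with identity-based self-exclusion.
4. **Immune signatures** — Ward hierarchical clustering of cases on
   z-scored log densities, plus a hot/excluded classification from the
   median-split pseudocounted tumor:stroma ratio.
5. **Survival** — median-dichotomized exposures in univariable and
   adjusted Cox proportional-hazards models of death within 5 years
   (Breslow ties, Newton-Raphson, Wald CIs), stratified by tumor
   morphology.

Every stage is validated against independent oracles (enumeration, brute
force, grid search) and against the generator's ground truth; see
[docs/methods.md](docs/methods.md) for the full methods note.

## Quick start

```python
from immunotopo import RunConfig, SimParams, generate_cohort, run_pipeline
from immunotopo.simulate import write_cohort

cohort = generate_cohort(SimParams(n_cases=12, cores_per_case=2, seed=21))
paths = write_cohort(cohort, "cohort/")
tables = run_pipeline(
    RunConfig(rng_seed=21),
    paths["cells_p1"], paths["cells_p2"],
    paths["geometry"], paths["clinical"],
    "out/",
)
```

This writes `phenotypes.csv`, `densities.csv`, `comparisons.csv`,
`spatial_summaries.csv`, `signatures.csv`, `hot_excluded.csv`,
`hazards.csv`, the learned `thresholds.yaml` and a `run_log.json`.
Re-running with the same seed reproduces every table byte for byte.

The same stages are available on the command line:

```bash
immunotopo simulate --seed 21 --out cohort/
immunotopo run --cells-p1 cohort/cells_p1.csv --cells-p2 cohort/cells_p2.csv \
    --geometry cohort/geometry.csv --clinical cohort/clinical.csv \
    --out out/
```

## Worked example

Running [examples/03_densities_and_comparisons.py](examples/03_densities_and_comparisons.py)
(12 synthetic cases, seed 5) gates panel 1, computes compartment densities
and tests the tumor-vs-stroma contrast:

```
            T_cell: median tumor     76.3  stroma    198.9 cells/mm²  (signed-rank p = 0.0005, exact)
   CD68_macrophage: median tumor     59.2  stroma    122.2 cells/mm²  (signed-rank p = 0.0005, exact)
         NKp46_NKT: median tumor     46.0  stroma     88.3 cells/mm²  (signed-rank p = 0.0005, exact)
                NK: median tumor     25.7  stroma     15.5 cells/mm²  (signed-rank p = 0.0093, exact)
```

Most immune classes are stroma-enriched, as the generator configures; the
gated labels agree with the generated ground truth for 99.7% of panel-1
cells ([examples/02_phenotype_gating.py](examples/02_phenotype_gating.py)).

On a clinical-scale cohort (n = 400) whose latent high-infiltration group
carries a true hazard ratio of 0.6, the Cox fitter recovers
([examples/06_survival.py](examples/06_survival.py)):

```
cases after exclusions: 387, events: 249
true HR 0.60 -> fitted HR 0.52 (95% CI 0.40-0.67, p = 4.6e-07)
```

And Ward clustering on the total-compartment density profiles separates
that latent group cleanly
([examples/05_signatures_hot_excluded.py](examples/05_signatures_hot_excluded.py)):

```
high-infiltration fraction per cluster:
  cluster 1: 0.00
  cluster 2: 1.00
  cluster 3: 0.00
  cluster 4: 1.00
```

The remaining examples cover cohort generation, spatial interactions and
the end-to-end pipeline; each prints its computed numbers when run with
`python examples/<name>.py`.

## Layout

```
src/immunotopo/
  io.py           readers, schema/integrity checks, exclusion rules
  config.py       run configuration and named seed streams
  simulate.py     synthetic TMA cohort generator with ground truth
  phenotyping.py  threshold learning, marker calls, gating cascade
  density.py      compartment-normalized densities
  ranktests.py    exact Wilcoxon signed-rank and Mann-Whitney U
  spatial.py      nearest-neighbor and interaction-zone statistics
  signatures.py   feature matrices, Ward clustering, hot/excluded
  survival.py     dataset assembly and Breslow/Newton Cox fitting
  pipeline.py     staged end-to-end runner
  cli.py          command-line interface
```
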