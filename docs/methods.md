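# Methods

This note documents the statistical and computational methods implemented in
`immunotopo`, a downstream spatial immunophenotyping pipeline for two-panel
multiplexed-immunofluorescence tissue-microarray (TMA) data.

## Data model

Cells carry a core identifier, a case identifier, micrometer coordinates, a
compartment (`tumor` or `stroma`) and one intensity column per marker.
Panel 1 stains CD3, NKp46, CD56, CD68, CD163 and cytokeratin (CK); panel 2
stains CD1a, CD208, CD123, CD15, CD68 and CK. Core geometry records
tumor/stroma areas in mm² and a tissue type (`malignant` or `benign`).
Clinical tables carry morphology (intestinal I-type vs pancreatobiliary
PB-type), standard clinicopathological covariates, exclusion flags and
follow-up. Cases flagged for neoadjuvant therapy are excluded from all
analyses; cases lost to follow-up or dying early postoperatively are
additionally excluded from survival analyses only.

## Marker thresholding and gating

For each marker, a two-component Gaussian mixture is fitted to
log(1 + intensity) on a random training subset of cores (default 25%,
seeded). The threshold is the intensity where the posterior probability of
the high component crosses 0.5, located on a fine grid refined by bisection.
If the two fitted modes are closer than 0.5 log-units the marker is treated
as effectively unimodal and the threshold falls back to the 95th percentile.
A cell is positive when its intensity strictly exceeds the threshold.

Phenotypes are assigned by a priority cascade over the six marker calls:

- **Panel 1.** CK+ → cancer. Otherwise CD3+ cells split by CD56/NKp46 into
  three disjoint NKT classes (CD56+NKp46+, CD56+ only, NKp46+ only); CD3+
  cells negative for both NK markers and for CD68/CD163 are T cells. CD3−
  CD56+NKp46+ cells are NK cells. CD3− myeloid cells split into
  CD68+CD163+, CD68+ and CD163+ classes. Everything else is `other`.
- **Panel 2.** CK+ → cancer. CD68+ cells are excluded from the
  dendritic-cell gates (→ `other`). Cells positive for exactly one of
  CD1a/CD208/CD123 are immature DC, mature DC or plasmacytoid DC
  respectively, or the corresponding CD15+ granulocyte class when CD15 is
  also positive. All other combinations are `other`.

The cascade is validated against an independent enumeration oracle over all
2⁶ marker-call signatures per panel.

## Densities

Per case, panel, phenotype and compartment, density = pooled cell count /
pooled area over the case's cores of the requested tissue type (ratio of
sums, never a mean of per-core ratios). The `total` compartment pools tumor
and stroma, so density·area is additive: counts in `total` equal
tumor + stroma exactly, and reconstruction of counts from density·area holds
to 1e-9.

## Rank tests

Tumor-vs-stroma contrasts use the Wilcoxon signed-rank test; group contrasts
(e.g. I-type vs PB-type) use the Mann-Whitney U test. Both are implemented
in-package so their exactness can be verified against enumeration oracles:

- Signed-rank: zero differences are dropped; |differences| are mid-ranked.
  For n ≤ 25 the exact null distribution is built by dynamic-programming
  convolution over doubled mid-ranks; otherwise a normal approximation with
  tie correction and continuity correction is used. Two-sided p = 2 × the
  smaller tail, capped at 1.
- Mann-Whitney: exact p by complete enumeration of labelings when the
  pooled sample is ≤ 12, else the tie-corrected normal approximation with
  continuity correction.

## Spatial statistics

Cells form a marked point pattern per core. For a reference class and a
target class, the nearest-neighbor distance of each reference cell is
computed with a k-d tree; self-matches are excluded by cell identity (not by
zero distance), so coincident distinct cells remain mutual neighbors.
Interaction counts are the number of neighbor-class cells within an
inclusive 15 μm radius of each reference cell. Distances and counts never
cross core boundaries. Per-case summaries pool cells across the case's
cores, weighting each cell equally. Queries are validated exactly against
an O(n²) brute-force oracle.

## Immune signatures and hot/excluded classification

For a given compartment view, the case × phenotype matrix of
log(1 + density) is assembled for the immune classes (cancer and `other`
are excluded); phenotypes present in fewer than 5% of cases and columns
with zero variance are dropped and reported. Columns are z-scored and cases
are clustered by agglomerative hierarchical clustering with Ward linkage on
Euclidean distance, cut at a configured number of clusters per view.
Labels are renumbered by descending cluster size, which also makes the
output invariant to row order.

Separately, each phenotype's infiltration ratio
(tumor density + ε) / (stroma density + ε) with pseudocount ε = 0.1
cells/mm² splits the cohort at its median: a case is `hot` iff its ratio
strictly exceeds the cohort median, else `excluded`; with both compartments
empty the ratio is exactly 1.

## Survival analysis

Continuous exposures (densities, spatial summaries) are dichotomized at the
cohort median (strictly above → `high`; ties → `low`). Follow-up is capped
at 60 months: deaths after the cap are recoded as censored at the cap.
Cox proportional-hazards models are fitted by Newton-Raphson on the Breslow
partial likelihood (suffix cumulative sums over the time-sorted design, step
halving, convergence when |Δ log-likelihood| < 1e-9, at most 100
iterations). Wald 95% confidence intervals are exp(β̂ ± 1.96·SE).
Multivariable models adjust for age, T-stage, N-stage, grade, adjuvant
chemotherapy, vascular and lymphatic invasion and perineural growth;
morphology is added only in entire-cohort analyses, not in the
morphology-stratified ones. A singular (collinear) design raises an error
naming the offending columns. Monotone likelihood (complete separation) is
detected via extreme coefficients or standard errors and is reported as a
flagged estimate with an infinite confidence bound, never as a finite
hazard ratio. Fits require ≥ 10 events and both exposure levels.

## Synthetic cohort generator

Each case receives a configurable number of 1 mm-diameter malignant cores
(and, for a fraction of cases, one benign core). The tumor compartment is a
union of random discs clipped to the core; compartment areas are measured by
numerical integration on a 2 μm grid. Per true class, cells are placed by a
homogeneous Poisson process at configured rates (cells/mm²) within their
compartment via rejection sampling. Marker intensities are log-normal:
positive mode exp(N(3.0, 0.4)) for the class-signature markers, negative
mode exp(N(0.5, 0.4)) otherwise. Panel 2 additionally contains a CD68+
population whose true downstream class is `other`, mirroring the
macrophages that the dendritic-cell gate excludes by design.

A latent high-infiltration group (half the cases) multiplies the NK/NKT
rates by 3 and enters the survival model with log-hazard ln 0.6.
Survival times follow a Weibull proportional-hazards model
t = scale·(−ln U / exp(lp))^(1/shape) with shape 1 and scale 50 months,
administratively censored at 120 months by default. All randomness derives
from a single top-level seed through named, CRC-keyed seed streams, so a
cohort and any pipeline run on it are bit-reproducible.

## Determinism

`run_pipeline` re-run with the same inputs, configuration and seed writes
byte-identical CSV tables. Stage seeds are logged to `run_log.json`
together with thresholds, exclusion decisions and filter reports.
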