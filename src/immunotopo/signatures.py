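"""Immune-infiltration signatures and hot/excluded classification.

Cases are clustered by their phenotype density profiles (one view per
compartment: total, tumor, stroma, or a combined view with externally
supplied lymphocyte densities) using agglomerative hierarchical clustering
with Ward linkage, after a log(1 + density) transform and per-column
z-scoring.  Separately, each phenotype's tumor:stroma infiltration ratio
splits the cohort at its median into immunologically hot (tumor-enriched)
versus immune-excluded cases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster

from .phenotyping import IMMUNE_CLASSES

__all__ = ["build_feature_matrix", "cluster_signatures", "classify_hot_excluded"]


def build_feature_matrix(
    densities: pd.DataFrame,
    view: str,
    min_prevalence: float = 0.05,
    extra_densities: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Case × phenotype matrix of standardized log densities for one view.

    Parameters
    ----------
    densities
        Output of :func:`immunotopo.density.compute_densities`.
    view
        ``"total"``, ``"tumor"`` or ``"stroma"`` — the compartment whose
        densities form the columns.
    min_prevalence
        Phenotypes present (density > 0) in fewer than this fraction of
        cases are dropped, mirroring the exclusion of vanishingly rare
        populations from clustering.
    extra_densities
        Optional additional densities in the same schema (e.g. previously
        published lymphocyte subsets) concatenated as extra columns for
        the combined view.

    Returns
    -------
    (matrix, dropped)
        `matrix` has one row per case and one z-scored column per retained
        phenotype; `dropped` names the phenotype columns removed by the
        prevalence or variance filters.
    """
    compartment = "total" if view == "combined" else view
    frames = [densities]
    if extra_densities is not None:
        frames.append(extra_densities)
    dens = pd.concat(frames, ignore_index=True)

    immune = {c for classes in IMMUNE_CLASSES.values() for c in classes}
    known = set(dens["phenotype"])
    keep = (immune | (known - immune)) - {"cancer", "other"}
    sub = dens[(dens["compartment"] == compartment)
               & dens["phenotype"].isin(keep)]
    wide = sub.pivot_table(index="case_id", columns="phenotype",
                           values="density", aggfunc="first")
    wide = wide.dropna(axis=0, how="any")

    dropped: list[str] = []
    prevalence = (wide > 0).mean(axis=0)
    for col in wide.columns[prevalence < min_prevalence]:
        dropped.append(str(col))
    wide = wide.drop(columns=[c for c in dropped])

    z = np.log1p(wide)
    sd = z.std(axis=0, ddof=1)
    # Relative tolerance: a constant column's sample sd is ~1e-16 due to
    # floating-point roundoff, never exactly zero.
    tol = 1e-10 * (1.0 + z.abs().mean(axis=0))
    zero_var = sd[(sd <= tol) | sd.isna()].index.tolist()
    dropped.extend(str(c) for c in zero_var)
    z = z.drop(columns=zero_var)
    z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)

    if z.shape[0] < 3:
        raise ValueError(f"only {z.shape[0]} cases after filtering; need >= 3")
    if z.shape[1] < 2:
        raise ValueError(f"only {z.shape[1]} columns after filtering; need >= 2")
    return z.sort_index(), sorted(dropped)


def cluster_signatures(matrix: pd.DataFrame, k: int) -> pd.Series:
    """Ward-linkage hierarchical clustering of cases, cut at `k` clusters.

    Labels are renumbered 1..k by descending cluster size (ties broken by
    the smallest case identifier in the cluster), so label 1 is always the
    largest signature.  Deterministic and invariant to row order.
    """
    n = matrix.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must be in [2, {n - 1}], got {k}")
    # Row order independence: cluster on a canonically sorted copy.
    m = matrix.sort_index()
    Z = linkage(m.to_numpy(dtype=float), method="ward", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=m.index, name="cluster")
    order = sorted(
        labels.groupby(labels).groups.items(),
        key=lambda kv: (-len(kv[1]), str(min(kv[1]))),
    )
    remap = {old: new for new, (old, _) in enumerate(order, start=1)}
    return labels.map(remap).reindex(matrix.index)


def classify_hot_excluded(
    densities: pd.DataFrame,
    phenotype: str,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Hot vs. immune-excluded classification by tumor:stroma ratio.

    ratio = (tumor density + ε) / (stroma density + ε) with pseudocount ε
    (cells/mm²); a case is ``hot`` iff its ratio strictly exceeds the
    cohort median of ratios for that phenotype, else ``excluded``.  With
    both compartments empty the ratio is exactly 1.
    """
    sub = densities[densities["phenotype"] == phenotype]
    tumor = sub[sub["compartment"] == "tumor"].set_index("case_id")["density"]
    stroma = sub[sub["compartment"] == "stroma"].set_index("case_id")["density"]
    cases = tumor.index.intersection(stroma.index)
    ratio = (tumor.loc[cases] + pseudocount) / (stroma.loc[cases] + pseudocount)
    ratio = ratio.dropna()
    med = float(ratio.median())
    label = np.where(ratio > med, "hot", "excluded")
    return pd.DataFrame({
        "case_id": ratio.index,
        "phenotype": phenotype,
        "ratio": ratio.to_numpy(dtype=float),
        "label": label,
    }).reset_index(drop=True)
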