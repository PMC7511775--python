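"""Compartment-normalized immune cell densities.

Densities are computed per case × phenotype × compartment by pooling cell
counts and viable areas over the case's cores (ratio of sums, not the mean
of per-core ratios), which keeps the estimator unbiased when cores differ
in viable area.  ``total`` uses the summed tumor + stroma area.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phenotyping import PHENOTYPE_SIGNATURES

__all__ = ["compute_densities"]


def compute_densities(
    phenotyped: pd.DataFrame,
    geometry: pd.DataFrame,
    tissue_type: str = "malignant",
    per_core: bool = False,
) -> pd.DataFrame:
    """Per case × panel × phenotype × compartment densities (cells/mm²).

    Parameters
    ----------
    phenotyped
        Cell table with a ``label`` column (output of the gating stage).
    geometry
        Per-core viable areas; every core referenced by `phenotyped` must
        appear here.
    tissue_type
        Restrict to cores of this tissue type (``"malignant"`` by default;
        pass ``"benign"`` for the paired benign analysis).
    per_core
        If True, group by core instead of case (one row per
        core × phenotype × compartment).

    Returns
    -------
    DataFrame with columns case_id, [core_id,] panel, phenotype,
    compartment (tumor|stroma|total), n_cells, area_mm2, density.
    Phenotypes with zero cells are emitted with density 0; compartments
    with zero pooled area get density NaN.
    """
    geo = geometry[geometry["tissue_type"] == tissue_type] \
        if "tissue_type" in geometry.columns else geometry
    known = set(geometry["core_id"])
    missing = set(phenotyped["core_id"]) - known
    if missing:
        raise ValueError(f"core(s) without geometry: {sorted(missing)}")

    cells = phenotyped[phenotyped["core_id"].isin(set(geo["core_id"]))]
    group_key = "core_id" if per_core else "case_id"

    # Pooled areas per group.
    areas = geo.groupby(group_key if per_core else "case_id").agg(
        tumor=("tumor_area_mm2", "sum"), stroma=("stroma_area_mm2", "sum")
    )
    areas["total"] = areas["tumor"] + areas["stroma"]
    core_to_case = geo.set_index("core_id")["case_id"]

    records = []
    counts = cells.groupby(
        [group_key, "panel", "label", "compartment"], observed=True
    ).size()

    for gid, row in areas.iterrows():
        case_id = core_to_case.get(gid, gid) if per_core else gid
        for panel, classes in PHENOTYPE_SIGNATURES.items():
            for phenotype in classes:
                n_tumor = int(counts.get((gid, panel, phenotype, "tumor"), 0))
                n_stroma = int(counts.get((gid, panel, phenotype, "stroma"), 0))
                for comp, n in (("tumor", n_tumor), ("stroma", n_stroma),
                                ("total", n_tumor + n_stroma)):
                    area = float(row[comp])
                    density = n / area if area > 0 else np.nan
                    rec = {"case_id": case_id, "panel": panel,
                           "phenotype": phenotype, "compartment": comp,
                           "n_cells": n, "area_mm2": area, "density": density}
                    if per_core:
                        rec["core_id"] = gid
                    records.append(rec)
    cols = ["case_id"] + (["core_id"] if per_core else []) + [
        "panel", "phenotype", "compartment", "n_cells", "area_mm2", "density"]
    return pd.DataFrame(records, columns=cols)
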