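"""Reading, validation and cohort exclusion rules for the three input tables.

All inputs are plain CSV with fixed column names:

* ``cells.csv`` — one row per segmented cell:
  ``cell_id,core_id,case_id,panel,x_um,y_um,compartment,int_<MARKER>...``
* ``geometry.csv`` — per-core viable areas:
  ``core_id,case_id,tumor_area_mm2,stroma_area_mm2[,tissue_type]``
* ``clinical.csv`` — one row per case with covariates, exclusion flags,
  survival time (months) and vital status; booleans as 0/1, missing empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phenotyping import PANEL_MARKERS

__all__ = [
    "SchemaError",
    "IntegrityError",
    "ExclusionResult",
    "CELL_BASE_COLUMNS",
    "CLINICAL_BOOL_COLUMNS",
    "read_cell_table",
    "write_cell_table",
    "read_geometry",
    "read_clinical",
    "apply_exclusions",
]


class SchemaError(ValueError):
    """A mandatory column is missing or malformed."""


class IntegrityError(ValueError):
    """Row-level invariant violated (negative intensity, duplicates, ...)."""


CELL_BASE_COLUMNS = (
    "cell_id", "core_id", "case_id", "panel", "x_um", "y_um", "compartment",
)

CLINICAL_BOOL_COLUMNS = (
    "adjuvant", "vascular_invasion", "lymphatic_invasion", "perineural_growth",
    "neoadjuvant", "lost_to_followup", "early_postop_death", "event",
)

_COMPARTMENTS = {"tumor", "stroma"}


def cell_columns(panel: str) -> list[str]:
    return list(CELL_BASE_COLUMNS) + [f"int_{m}" for m in PANEL_MARKERS[panel]]


def read_cell_table(path, panel: str) -> pd.DataFrame:
    """Read and validate a per-cell table for one panel.

    Raises
    ------
    SchemaError
        When a mandatory column for the stated panel is absent.
    IntegrityError
        When rows violate invariants (unknown compartment, negative
        intensity, non-finite coordinates) or (core_id, cell_id) pairs are
        duplicated; the message lists the offending row indices.
    """
    df = pd.read_csv(path, dtype={"cell_id": str, "core_id": str, "case_id": str})
    required = cell_columns(panel)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    bad: dict[str, list[int]] = {}
    comp_bad = df.index[~df["compartment"].isin(_COMPARTMENTS)].tolist()
    if comp_bad:
        bad["unknown compartment"] = comp_bad
    coords = df[["x_um", "y_um"]].to_numpy(dtype=float)
    coord_bad = df.index[~np.isfinite(coords).all(axis=1)].tolist()
    if coord_bad:
        bad["non-finite coordinates"] = coord_bad
    for m in PANEL_MARKERS[panel]:
        col = df[f"int_{m}"].to_numpy(dtype=float)
        neg = df.index[(col < 0) | ~np.isfinite(col)].tolist()
        if neg:
            bad[f"negative or non-finite int_{m}"] = neg
    if bad:
        msg = "; ".join(f"{reason}: rows {rows}" for reason, rows in bad.items())
        raise IntegrityError(msg)

    dup = df.duplicated(subset=["core_id", "cell_id"], keep=False)
    if dup.any():
        raise IntegrityError(
            f"duplicate (core_id, cell_id): rows {df.index[dup].tolist()}"
        )
    wrong_panel = df.index[df["panel"] != panel].tolist()
    if wrong_panel:
        raise IntegrityError(f"panel mismatch (expected {panel}): rows {wrong_panel}")
    return df[required].copy()


def write_cell_table(cells: pd.DataFrame, path) -> None:
    panel = cells["panel"].iloc[0] if len(cells) else "P1"
    cells.to_csv(path, index=False, columns=cell_columns(panel))


def read_geometry(path) -> pd.DataFrame:
    """Read per-core viable tumor/stroma areas (mm²)."""
    df = pd.read_csv(path, dtype={"core_id": str, "case_id": str})
    required = ["core_id", "case_id", "tumor_area_mm2", "stroma_area_mm2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    if "tissue_type" not in df.columns:
        df["tissue_type"] = "malignant"
    areas = df[["tumor_area_mm2", "stroma_area_mm2"]].to_numpy(dtype=float)
    if (areas < 0).any() or not np.isfinite(areas).all():
        raise IntegrityError("negative or non-finite areas in geometry table")
    if (areas.sum(axis=1) <= 0).any():
        bad = df.index[areas.sum(axis=1) <= 0].tolist()
        raise IntegrityError(f"core with zero total viable area: rows {bad}")
    if df["core_id"].duplicated().any():
        raise IntegrityError("duplicate core_id in geometry table")
    return df


def read_clinical(path) -> pd.DataFrame:
    """Read the per-case clinical table; boolean flags coerced to bool."""
    df = pd.read_csv(path, dtype={"case_id": str})
    required = ["case_id", "morphology", "os_months", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    if df["case_id"].duplicated().any():
        raise IntegrityError("duplicate case_id in clinical table")
    if (df["os_months"].to_numpy(dtype=float) < 0).any():
        raise IntegrityError("negative os_months")
    for col in CLINICAL_BOOL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].fillna(0).astype(int).astype(bool)
    for col in df.columns:
        if col.startswith("mut_"):
            df[col] = df[col].fillna(0).astype(int).astype(bool)
    return df


@dataclass
class ExclusionResult:
    """Case sets after applying the cohort exclusion rules.

    ``general`` drives all descriptive statistics; ``survival`` is the
    (smaller) set entering survival analyses; ``excluded`` lists each
    excluded case with its reason and the scope of the exclusion.
    """

    general: pd.DataFrame
    survival: pd.DataFrame
    excluded: pd.DataFrame

    @property
    def general_cases(self) -> set:
        return set(self.general["case_id"])

    @property
    def survival_cases(self) -> set:
        return set(self.survival["case_id"])


def apply_exclusions(clinical: pd.DataFrame) -> ExclusionResult:
    """Apply the cohort's exclusion rules.

    Neoadjuvantly treated cases are removed from all statistics; cases lost
    to follow-up and early postoperative deaths are removed from survival
    analyses only.  The survival case set is therefore always a subset of
    the general-statistics set.
    """
    df = clinical.copy()
    for col in ("neoadjuvant", "lost_to_followup", "early_postop_death"):
        if col not in df.columns:
            df[col] = False

    records = []
    neo = df["neoadjuvant"].astype(bool)
    for cid in df.loc[neo, "case_id"]:
        records.append({"case_id": cid, "reason": "neoadjuvant therapy",
                        "scope": "all"})
    general = df[~neo].copy()

    ltf = general["lost_to_followup"].astype(bool)
    epd = general["early_postop_death"].astype(bool) & ~ltf
    for cid in general.loc[ltf, "case_id"]:
        records.append({"case_id": cid, "reason": "lost to follow-up",
                        "scope": "survival"})
    for cid in general.loc[epd, "case_id"]:
        records.append({"case_id": cid, "reason": "early postoperative death",
                        "scope": "survival"})
    survival = general[~(ltf | epd)].copy()

    excluded = pd.DataFrame(records, columns=["case_id", "reason", "scope"])
    return ExclusionResult(general=general, survival=survival, excluded=excluded)
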