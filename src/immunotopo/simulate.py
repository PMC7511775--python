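"""Synthetic TMA cohort generator with known ground truth.

Emulates the structure of a multiplexed-immunofluorescence tissue-microarray
study: 1 mm circular cores containing tumor nests (random discs) in a
stromal background, per-class homogeneous Poisson cell placement, bimodal
log-normal marker intensities keyed to the phenotype signatures used by the
gater, clinical covariates and Weibull proportional-hazards survival times
with known coefficients.  Every generated cell carries its true phenotype
label, so downstream stages can be validated against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .phenotyping import PANEL_MARKERS, PHENOTYPE_SIGNATURES

__all__ = ["SimParams", "CohortData", "generate_core", "generate_cohort",
           "write_cohort", "default_class_intensity"]


def default_class_intensity() -> dict:
    """Expected cells/mm² per (panel, class, compartment).

    Chosen to resemble a periampullary-adenocarcinoma microenvironment:
    dense cytokeratin-positive epithelium inside tumor nests, macrophages
    the most abundant innate class and enriched in stroma, NK/NKT cells
    sparse, mature dendritic cells and two granulocyte classes rare enough
    to trip prevalence filters downstream.
    """
    return {
        "P1": {
            "cancer": {"tumor": 1500.0, "stroma": 0.0},
            "CD68_macrophage": {"tumor": 60.0, "stroma": 120.0},
            "CD163_myeloid": {"tumor": 10.0, "stroma": 25.0},
            "CD68_CD163_macrophage": {"tumor": 8.0, "stroma": 20.0},
            "NK": {"tumor": 8.0, "stroma": 5.0},
            "CD56_NKT": {"tumor": 10.0, "stroma": 20.0},
            "NKp46_NKT": {"tumor": 15.0, "stroma": 30.0},
            "CD56_NKp46_NKT": {"tumor": 5.0, "stroma": 10.0},
            "T_cell": {"tumor": 80.0, "stroma": 200.0},
            "other": {"tumor": 150.0, "stroma": 300.0},
        },
        "P2": {
            "cancer": {"tumor": 1500.0, "stroma": 0.0},
            "iDC": {"tumor": 25.0, "stroma": 10.0},
            "mDC": {"tumor": 1.0, "stroma": 2.0},
            "pDC": {"tumor": 8.0, "stroma": 12.0},
            "CD1a_CD15_granulocyte": {"tumor": 0.5, "stroma": 1.0},
            "CD208_CD15_granulocyte": {"tumor": 0.5, "stroma": 1.0},
            "CD123_CD15_granulocyte": {"tumor": 15.0, "stroma": 10.0},
            "other_CD68": {"tumor": 40.0, "stroma": 80.0},
            "other": {"tumor": 200.0, "stroma": 350.0},
        },
    }


#: NK/NKT family whose rates are scaled up in latent high-infiltration cases.
_HIGH_GROUP_CLASSES = ("NK", "CD56_NKT", "NKp46_NKT", "CD56_NKp46_NKT")

#: Generator-only populations absent from the gating taxonomy.  Panel 2
#: tissue contains CD68+ macrophages; the dendritic-cell gate excludes them
#: by design, so their true downstream class is "other" even though their
#: CD68 channel is genuinely positive.
_EXTRA_POPULATIONS = {
    "P2": {"other_CD68": (frozenset({"CD68"}), "other")},
}

#: Rate multipliers applied to benign (tumor-free) cores relative to
#: malignant ones: NK/NKT higher, myeloid/DC/granulocyte lower.
_BENIGN_MULTIPLIER = {
    "NK": 2.5, "CD56_NKT": 2.5, "NKp46_NKT": 2.5, "CD56_NKp46_NKT": 2.5,
    "CD68_macrophage": 0.5, "CD163_myeloid": 0.5, "CD68_CD163_macrophage": 0.5,
    "iDC": 0.5, "mDC": 0.5, "pDC": 0.5,
    "CD1a_CD15_granulocyte": 0.5, "CD208_CD15_granulocyte": 0.5,
    "CD123_CD15_granulocyte": 0.5, "other_CD68": 0.5,
    "cancer": 0.0,
}


@dataclass
class SimParams:
    """Parameters of the synthetic cohort.

    Geometry is a 1 mm-diameter core (radius 500 μm) whose tumor compartment
    is a union of random discs; compartment areas are measured by numerical
    integration on a 2 μm grid, the same pitch the imaging platform's
    2 px/μm resolution implies.  Survival times follow a Weibull baseline
    (shape 1, scale 50 months) under a log-linear proportional-hazards model
    with the configured coefficients; the latent high-infiltration group
    (NK/NKT rates scaled by ``high_group_multiplier``) carries a protective
    log-hazard of ln 0.6 by default.
    """

    n_cases: int = 40
    cores_per_case: int = 3
    core_radius: float = 500.0          # μm
    n_tumor_nests: int = 6
    nest_radius_logmean: float = math.log(90.0)  # log μm
    nest_radius_logsd: float = 0.4
    grid_pitch: float = 2.0             # μm, area integration pitch
    class_intensity: dict = field(default_factory=default_class_intensity)
    marker_pos_logmean: float = 3.0
    marker_pos_logsd: float = 0.4
    marker_neg_logmean: float = 0.5
    marker_neg_logsd: float = 0.4
    high_group_multiplier: float = 3.0
    benign_case_fraction: float = 0.2
    betas: dict = field(default_factory=lambda: {
        "high_infiltration": math.log(0.6),
        "t_stage": 0.4,
        "n_stage": 0.5,
    })
    baseline_weibull_shape: float = 1.0
    baseline_weibull_scale: float = 50.0  # months
    admin_censor_months: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_radius <= 0:
            raise ValueError("core_radius must be > 0")
        if self.marker_pos_logmean <= self.marker_neg_logmean:
            raise ValueError("marker_pos_logmean must exceed marker_neg_logmean")
        core_area_mm2 = math.pi * (self.core_radius / 1000.0) ** 2
        for panel, classes in self.class_intensity.items():
            for cls, rates in classes.items():
                for comp, r in rates.items():
                    if r < 0:
                        raise ValueError(f"negative rate for {panel}/{cls}/{comp}")
                    if r * core_area_mm2 > 1e6:
                        raise ValueError(
                            f"rate {r} for {panel}/{cls}/{comp} implies more "
                            "than 1e6 cells per core"
                        )


@dataclass
class CohortData:
    cells: pd.DataFrame          # both panels, all cores
    geometry: pd.DataFrame
    clinical: pd.DataFrame
    cell_truth: pd.DataFrame     # cell_id, core_id, panel, true_label
    case_truth: pd.DataFrame     # case_id, high_infiltration, linear_predictor
    params: SimParams


def _sample_in_disc(rng: np.random.Generator, n: int, radius: float,
                    center: tuple[float, float]) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = 2.0 * math.pi * rng.random(n)
    return np.column_stack([center[0] + r * np.cos(theta),
                            center[1] + r * np.sin(theta)])


def generate_core(
    params: SimParams,
    case_id: str,
    core_index: int,
    rng: np.random.Generator,
    *,
    tissue_type: str = "malignant",
    rate_multiplier: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Generate one core: cells for both panels, geometry, ground truth.

    The tumor compartment is the union of random discs clipped to the core
    disc; benign cores (``tissue_type="benign"``) have no tumor nests.
    Per true class, cells are placed by a homogeneous Poisson process at
    the configured rate within their compartment, and marker intensities
    are drawn log-normally: positive mode for the class-signature markers,
    negative mode otherwise.
    """
    R = params.core_radius
    center = (R, R)
    core_id = f"{case_id}-core{core_index}"

    if tissue_type == "benign" or params.n_tumor_nests == 0:
        nests = np.empty((0, 3))
    else:
        n_nests = params.n_tumor_nests
        centers = _sample_in_disc(rng, n_nests, R, center)
        radii = np.exp(rng.normal(params.nest_radius_logmean,
                                  params.nest_radius_logsd, n_nests))
        nests = np.column_stack([centers, radii])

    def in_tumor(xy: np.ndarray) -> np.ndarray:
        if nests.shape[0] == 0:
            return np.zeros(len(xy), dtype=bool)
        d2 = ((xy[:, None, :] - nests[None, :, :2]) ** 2).sum(axis=2)
        return (d2 <= nests[None, :, 2] ** 2).any(axis=1)

    # Grid integration of compartment areas at grid_pitch resolution.
    pitch = params.grid_pitch
    ax = np.arange(pitch / 2.0, 2 * R, pitch)
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    in_core = ((pts[:, 0] - R) ** 2 + (pts[:, 1] - R) ** 2) <= R ** 2
    core_pts = pts[in_core]
    tumor_mask = in_tumor(core_pts)
    px_mm2 = pitch * pitch * 1e-6
    tumor_area = float(tumor_mask.sum() * px_mm2)
    stroma_area = float((~tumor_mask).sum() * px_mm2)

    geometry = {
        "core_id": core_id, "case_id": case_id,
        "tumor_area_mm2": tumor_area, "stroma_area_mm2": stroma_area,
        "tissue_type": tissue_type,
    }

    mult = rate_multiplier or {}
    rows, truth_rows = [], []
    for panel in ("P1", "P2"):
        markers = PANEL_MARKERS[panel]
        sigs = PHENOTYPE_SIGNATURES[panel]
        extra = _EXTRA_POPULATIONS.get(panel, {})
        counter = 0
        for cls in params.class_intensity[panel]:  # dict order -> deterministic
            if cls in sigs:
                pos_markers, true_label = sigs[cls], cls
            elif cls in extra:
                pos_markers, true_label = extra[cls]
            else:
                raise ValueError(f"unknown generation class {cls!r} for {panel}")
            for comp, area in (("tumor", tumor_area), ("stroma", stroma_area)):
                rate = params.class_intensity[panel][cls][comp]
                rate *= mult.get(cls, 1.0)
                if tissue_type == "benign":
                    rate *= _BENIGN_MULTIPLIER.get(cls, 1.0)
                n = int(rng.poisson(rate * area)) if area > 0 else 0
                if n == 0:
                    continue
                # Rejection-sample n points uniformly in the compartment.
                placed = np.empty((0, 2))
                attempts = 0
                while len(placed) < n and attempts < 1000:
                    batch = _sample_in_disc(rng, max(4 * n, 64), R, center)
                    keep = in_tumor(batch) == (comp == "tumor")
                    placed = np.vstack([placed, batch[keep]])
                    attempts += 1
                placed = placed[:n]
                pos = pos_markers
                ids = [f"{core_id}-{panel}-{counter + i}" for i in range(n)]
                counter += n
                batch = pd.DataFrame({
                    "cell_id": ids, "core_id": core_id, "case_id": case_id,
                    "panel": panel,
                    "x_um": np.round(placed[:, 0], 3),
                    "y_um": np.round(placed[:, 1], 3),
                    "compartment": comp,
                })
                for m in markers:
                    if m in pos:
                        v = rng.lognormal(params.marker_pos_logmean,
                                          params.marker_pos_logsd, n)
                    else:
                        v = rng.lognormal(params.marker_neg_logmean,
                                          params.marker_neg_logsd, n)
                    batch[f"int_{m}"] = np.round(v, 4)
                rows.append(batch)
                truth_rows.append(pd.DataFrame({
                    "cell_id": ids, "core_id": core_id, "case_id": case_id,
                    "panel": panel, "true_label": true_label,
                }))

    base = ["cell_id", "core_id", "case_id", "panel", "x_um", "y_um",
            "compartment"]
    all_markers = list(PANEL_MARKERS["P1"]) + [
        m for m in PANEL_MARKERS["P2"] if m not in PANEL_MARKERS["P1"]
    ]
    columns = base + [f"int_{m}" for m in all_markers]
    if rows:
        cells = pd.concat(rows, ignore_index=True).reindex(columns=columns)
        truth = pd.concat(truth_rows, ignore_index=True)
    else:
        cells = pd.DataFrame(columns=columns)
        truth = pd.DataFrame(
            columns=["cell_id", "core_id", "case_id", "panel", "true_label"]
        )
    return cells, geometry, truth


_ORIGINS = ("duodenal", "ampullary", "distal bile duct", "pancreatic")
_ORIGIN_P = (0.08, 0.40, 0.26, 0.26)
_MUTATION_P = {"KRAS": 0.55, "TP53": 0.50, "APC": 0.12,
               "SMAD4": 0.25, "CDKN2A": 0.20}


def generate_cohort(params: SimParams) -> CohortData:
    """Generate a full cohort: cells (both panels), geometry, clinical, truth.

    Each case gets ``cores_per_case`` malignant cores; a random
    ``benign_case_fraction`` of cases additionally contribute one benign
    (tumor-free) core, mirroring paired benign tissue.  A latent
    high-infiltration group scales the NK/NKT rates and enters the
    proportional-hazards linear predictor with its configured coefficient.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    n = params.n_cases
    case_ids = [f"case{str(i).zfill(3)}" for i in range(n)]

    morphology = np.where(rng.random(n) < 65 / 175, "I-type", "PB-type")
    origin = rng.choice(_ORIGINS, size=n, p=_ORIGIN_P)
    age = np.clip(np.round(rng.normal(70, 8, n), 1), 40, 90)
    t_stage = np.where(rng.random(n) < 0.7, "T3_T4", "T1_T2")
    n_stage = np.where(rng.random(n) < 0.6, "positive", "negative")
    grade = np.where(rng.random(n) < 0.45, "poor", "well_moderate")
    adjuvant = rng.random(n) < 0.5
    vascular = rng.random(n) < 0.35
    lymphatic = rng.random(n) < 0.5
    perineural = rng.random(n) < 0.6
    neoadjuvant = rng.random(n) < 0.01
    lost = rng.random(n) < 0.005
    early_death = rng.random(n) < 0.01
    mmr = np.where(rng.random(n) < 0.10, "deficient", "proficient")
    mutations = {g: rng.random(n) < p for g, p in _MUTATION_P.items()}
    high = rng.random(n) < 0.5

    # Proportional-hazards linear predictor over configured coefficients.
    covariate_values = {
        "high_infiltration": high.astype(float),
        "age": (age - 70.0) / 10.0,
        "t_stage": (t_stage == "T3_T4").astype(float),
        "n_stage": (n_stage == "positive").astype(float),
        "grade": (grade == "poor").astype(float),
        "adjuvant": adjuvant.astype(float),
        "vascular_invasion": vascular.astype(float),
        "lymphatic_invasion": lymphatic.astype(float),
        "perineural_growth": perineural.astype(float),
        "morphology": (morphology == "PB-type").astype(float),
    }
    lp = np.zeros(n)
    for key, beta in params.betas.items():
        if key not in covariate_values:
            raise ValueError(f"unknown beta covariate {key!r}")
        lp += beta * covariate_values[key]

    shape = params.baseline_weibull_shape
    scale = params.baseline_weibull_scale
    u = rng.random(n)
    t_event = scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)
    censor = params.admin_censor_months
    os_months = np.round(np.minimum(t_event, censor), 2)
    event = t_event <= censor

    clinical = pd.DataFrame({
        "case_id": case_ids, "morphology": morphology, "origin": origin,
        "age": age, "t_stage": t_stage, "n_stage": n_stage, "grade": grade,
        "adjuvant": adjuvant, "vascular_invasion": vascular,
        "lymphatic_invasion": lymphatic, "perineural_growth": perineural,
        "neoadjuvant": neoadjuvant, "lost_to_followup": lost,
        "early_postop_death": early_death, "mmr": mmr,
        **{f"mut_{g}": v for g, v in mutations.items()},
        "os_months": os_months, "event": event,
    })

    n_benign = int(round(params.benign_case_fraction * n))
    benign_cases = set(
        rng.choice(np.array(case_ids), size=n_benign, replace=False)
    ) if n_benign else set()

    all_cells, geoms, truths = [], [], []
    for i, cid in enumerate(case_ids):
        mult = ({c: params.high_group_multiplier for c in _HIGH_GROUP_CLASSES}
                if high[i] else None)
        for k in range(params.cores_per_case):
            cells, geom, truth = generate_core(
                params, cid, k, rng, tissue_type="malignant",
                rate_multiplier=mult,
            )
            all_cells.append(cells)
            geoms.append(geom)
            truths.append(truth)
        if cid in benign_cases:
            cells, geom, truth = generate_core(
                params, cid, params.cores_per_case, rng,
                tissue_type="benign", rate_multiplier=mult,
            )
            all_cells.append(cells)
            geoms.append(geom)
            truths.append(truth)

    base = ["cell_id", "core_id", "case_id", "panel", "x_um", "y_um",
            "compartment"]
    all_markers = list(PANEL_MARKERS["P1"]) + [
        m for m in PANEL_MARKERS["P2"] if m not in PANEL_MARKERS["P1"]
    ]
    if all_cells:
        cells = pd.concat(all_cells, ignore_index=True)
        cell_truth = pd.concat(truths, ignore_index=True)
    else:  # clinical-only cohort (cores_per_case = 0)
        cells = pd.DataFrame(columns=base + [f"int_{m}" for m in all_markers])
        cell_truth = pd.DataFrame(
            columns=["cell_id", "core_id", "case_id", "panel", "true_label"])
    geometry = pd.DataFrame(
        geoms, columns=["core_id", "case_id", "tumor_area_mm2",
                        "stroma_area_mm2", "tissue_type"])
    case_truth = pd.DataFrame({
        "case_id": case_ids,
        "high_infiltration": high,
        "linear_predictor": lp,
        "uncensored_time": t_event,
    })
    return CohortData(cells=cells, geometry=geometry, clinical=clinical,
                      cell_truth=cell_truth, case_truth=case_truth,
                      params=params)


def write_cohort(cohort: CohortData, out_dir) -> dict[str, Path]:
    """Write the cohort as the CSV files the reading layer consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for panel in ("P1", "P2"):
        sub = cohort.cells[cohort.cells["panel"] == panel]
        cols = ["cell_id", "core_id", "case_id", "panel", "x_um", "y_um",
                "compartment"] + [f"int_{m}" for m in PANEL_MARKERS[panel]]
        p = out / f"cells_{panel.lower()}.csv"
        sub[cols].to_csv(p, index=False)
        paths[f"cells_{panel.lower()}"] = p
    for name, df in (("geometry", cohort.geometry),
                     ("clinical", cohort.clinical),
                     ("ground_truth", cohort.cell_truth)):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
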