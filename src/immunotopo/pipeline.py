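"""End-to-end pipeline: gating → densities → spatial → signatures → survival.

Each stage consumes the previous stage's tables, writes a CSV under the
output directory, and logs its seed and decisions to ``run_log.json``.
Re-running with the same seed and inputs reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as iomod
from .config import RunConfig
from .density import compute_densities
from .phenotyping import (IMMUNE_CLASSES, assign_phenotypes, call_markers,
                          derive_thresholds)
from .ranktests import mann_whitney_u, wilcoxon_signed_rank
from .signatures import (build_feature_matrix, classify_hot_excluded,
                         cluster_signatures)
from .spatial import per_case_interaction_summary, per_case_nearest_summary
from .survival import (MULTIVARIABLE_COVARIATES, build_survival_dataset,
                       cox_fit, dichotomize_at_median)

__all__ = ["PipelineError", "run_pipeline"]

#: Reference classes whose interaction zones are profiled against the
#: other panel-1 immune classes and cancer cells.
INTERACTION_REFERENCES = ("NKp46_NKT", "CD68_macrophage")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


@_stage("gating")
def _run_gating(config, cells_p1_path, cells_p2_path, log, include_cases=None):
    phenotyped = {}
    thresholds = {}
    for panel, path in (("P1", cells_p1_path), ("P2", cells_p2_path)):
        cells = iomod.read_cell_table(path, panel)
        if include_cases is not None:
            cells = cells[cells["case_id"].isin(include_cases)]
        seed = config.seed_for(f"thresholds_{panel}")
        thr = derive_thresholds(
            cells, panel,
            training_fraction=config.threshold_training_fraction,
            seed=seed,
        )
        calls = call_markers(cells, thr)
        cells = cells.copy()
        cells["label"] = assign_phenotypes(calls, panel)
        phenotyped[panel] = cells
        thresholds[panel] = thr
        log.setdefault("seeds", {})[f"thresholds_{panel}"] = seed
        log.setdefault("thresholds", {})[panel] = {
            "values": thr.thresholds, "provenance": thr.provenance,
        }
    return pd.concat(phenotyped.values(), ignore_index=True), thresholds


@_stage("densities")
def _run_densities(config, phenotyped, geometry_path, clinical, log):
    geometry = iomod.read_geometry(geometry_path)
    densities = compute_densities(phenotyped, geometry, tissue_type="malignant")
    has_benign = ("tissue_type" in geometry.columns
                  and (geometry["tissue_type"] == "benign").any())
    benign = (compute_densities(phenotyped, geometry, tissue_type="benign")
              if has_benign else None)

    comparisons = []
    morph = clinical.set_index("case_id")["morphology"]
    for panel, classes in IMMUNE_CLASSES.items():
        for phenotype in classes:
            sub = densities[densities["phenotype"] == phenotype]
            wide = sub.pivot_table(index="case_id", columns="compartment",
                                   values="density", aggfunc="first")
            pair = wide[["tumor", "stroma"]].dropna()
            if len(pair) >= 2:
                res = wilcoxon_signed_rank(pair["tumor"], pair["stroma"])
                comparisons.append({
                    "phenotype": phenotype, "compartment": "tumor_vs_stroma",
                    "grouping": "paired", "test": "wilcoxon_signed_rank",
                    "statistic": res.statistic, "p": res.p, "n": res.n,
                })
            total = sub[sub["compartment"] == "total"].set_index("case_id")["density"]
            m = morph.reindex(total.index)
            gi = total[m == "I-type"].dropna()
            gp = total[m == "PB-type"].dropna()
            if len(gi) and len(gp):
                res = mann_whitney_u(gi, gp)
                comparisons.append({
                    "phenotype": phenotype,
                    "compartment": "total",
                    "grouping": "I-type_vs_PB-type",
                    "test": "mann_whitney_u",
                    "statistic": res.statistic, "p": res.p, "n": res.n,
                })
            if benign is not None:
                btot = benign[(benign["phenotype"] == phenotype)
                              & (benign["compartment"] == "total")]
                btot = btot.set_index("case_id")["density"].dropna()
                common = btot.index.intersection(total.dropna().index)
                if len(common) >= 2:
                    res = wilcoxon_signed_rank(total.loc[common], btot.loc[common])
                    comparisons.append({
                        "phenotype": phenotype, "compartment": "total",
                        "grouping": "malignant_vs_benign_paired",
                        "test": "wilcoxon_signed_rank",
                        "statistic": res.statistic, "p": res.p, "n": res.n,
                    })
    comparisons = pd.DataFrame(comparisons)
    if config.adjust_pvalues and len(comparisons):
        comparisons["p_adj"] = _benjamini_hochberg(comparisons["p"].to_numpy())
    return densities, benign, comparisons


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


@_stage("spatial")
def _run_spatial(config, phenotyped, log):
    frames = []
    # Mean distance from each cancer cell to the nearest cell of every
    # immune class, per panel.
    for panel, classes in IMMUNE_CLASSES.items():
        panel_cells = phenotyped[phenotyped["panel"] == panel]
        for target in classes:
            frames.append(
                per_case_nearest_summary(panel_cells, "cancer", target)
            )
    # Interaction-zone profiles of the reference classes (panel 1).
    p1 = phenotyped[phenotyped["panel"] == "P1"]
    for ref in INTERACTION_REFERENCES:
        for neighbor in list(IMMUNE_CLASSES["P1"]) + ["cancer"]:
            if neighbor == ref:
                continue
            frames.append(per_case_interaction_summary(
                p1, ref, neighbor, radius=config.interaction_radius,
            ))
    return pd.concat(frames, ignore_index=True)


@_stage("signatures")
def _run_signatures(config, densities, log, extra_densities=None):
    sig_rows = []
    for view, k in sorted(config.cluster_k.items()):
        if view == "combined" and extra_densities is None:
            log.setdefault("signatures", {})[view] = "skipped: no external densities"
            continue
        matrix, dropped = build_feature_matrix(
            densities, view, min_prevalence=config.min_prevalence,
            extra_densities=extra_densities if view == "combined" else None,
        )
        if k >= matrix.shape[0]:
            log.setdefault("signatures", {})[view] = (
                f"skipped: k={k} infeasible for {matrix.shape[0]} cases")
            continue
        labels = cluster_signatures(matrix, k)
        log.setdefault("signatures", {})[view] = {"k": k, "dropped": dropped}
        for case_id, cluster in labels.items():
            sig_rows.append({"case_id": case_id, "view": view, "k": k,
                             "cluster": int(cluster)})
    signatures = pd.DataFrame(sig_rows,
                              columns=["case_id", "view", "k", "cluster"])

    hot_rows = []
    n_cases = densities["case_id"].nunique()
    for panel, classes in IMMUNE_CLASSES.items():
        for phenotype in classes:
            sub = densities[(densities["phenotype"] == phenotype)
                            & (densities["compartment"] == "total")]
            prevalence = (sub["density"] > 0).sum() / max(n_cases, 1)
            if prevalence < config.min_prevalence:
                log.setdefault("hot_excluded_skipped", []).append(phenotype)
                continue
            hot_rows.append(classify_hot_excluded(
                densities, phenotype, pseudocount=config.ratio_pseudocount,
            ))
    hot = (pd.concat(hot_rows, ignore_index=True)
           if hot_rows else pd.DataFrame(
               columns=["case_id", "phenotype", "ratio", "label"]))
    return signatures, hot


@_stage("survival")
def _run_survival(config, densities, spatial_summaries, signatures, hot,
                  clinical, log):
    exposures: dict[str, pd.Series] = {}

    for (phenotype, compartment), grp in densities.groupby(
            ["phenotype", "compartment"]):
        if phenotype in ("cancer", "other"):
            continue
        vals = grp.set_index("case_id")["density"]
        if vals.notna().sum() >= 2 and vals.dropna().nunique() > 1:
            exposures[f"density:{phenotype}:{compartment}"] = vals

    for (ref, neighbor, metric), grp in spatial_summaries.groupby(
            ["reference", "neighbor", "metric"]):
        vals = grp.set_index("case_id")["value"]
        if vals.notna().sum() >= 2 and vals.dropna().nunique() > 1:
            exposures[f"spatial:{metric}:{ref}->{neighbor}"] = vals

    estimates = []
    strata = ("all", "I-type", "PB-type")
    for name, values in sorted(exposures.items()):
        binary = dichotomize_at_median(values)
        for stratum in strata:
            for model in ("univariable", "multivariable"):
                est = _fit_one(clinical, binary, name, stratum, model, config)
                if est is not None:
                    estimates.append(est)

    # Hot vs excluded classifications as binary exposures.
    for phenotype, grp in hot.groupby("phenotype"):
        labels = grp.set_index("case_id")["label"].map(
            {"excluded": "low", "hot": "high"})
        for stratum in strata:
            for model in ("univariable", "multivariable"):
                est = _fit_one(clinical, labels, f"hot_excluded:{phenotype}",
                               stratum, model, config)
                if est is not None:
                    estimates.append(est)

    # Cluster signatures: indicator per non-reference cluster, reference =
    # cluster 1 (the largest).
    for view, grp in signatures.groupby("view"):
        clusters = grp.set_index("case_id")["cluster"]
        for c in sorted(clusters.unique()):
            if c == 1:
                continue
            indicator = clusters.isin([1, c])
            sub = clusters[indicator].map(lambda v: "high" if v == c else "low")
            for stratum in strata:
                for model in ("univariable", "multivariable"):
                    est = _fit_one(
                        clinical, sub,
                        f"signature:{view}:cluster{c}_vs_cluster1",
                        stratum, model, config)
                    if est is not None:
                        estimates.append(est)

    rows = [dataclasses.asdict(e) for e in estimates]
    return pd.DataFrame(rows, columns=[
        "variable", "stratum", "model", "hr", "ci_low", "ci_high",
        "n", "n_events", "p", "flag"])


def _fit_one(clinical, exposure, name, stratum, model, config):
    """Fit one Cox model; returns None when preconditions fail."""
    try:
        data = build_survival_dataset(
            clinical, exposure, stratum=stratum, cap=config.followup_cap)
    except ValueError:
        return None
    if data["event"].sum() < 10:
        return None
    if data["exposure"].nunique() < 2:
        return None
    if model == "univariable":
        cols = ["exposure"]
    else:
        cols = ["exposure"] + [c for c in data.columns
                               if c not in ("case_id", "time", "event",
                                            "exposure")]
    try:
        res = cox_fit(data, cols)
    except ValueError:
        return None
    est = res.hazard_estimate("exposure", stratum=stratum, model=model)
    est.variable = name
    return est


def run_pipeline(
    config: RunConfig,
    cells_p1_path,
    cells_p2_path,
    geometry_path,
    clinical_path,
    out_dir,
    lymphocyte_densities_path=None,
) -> dict:
    """Execute all stages and write per-stage CSV outputs.

    Returns a dict of the in-memory tables.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": dataclasses.asdict(config)}

    try:
        clinical = iomod.read_clinical(clinical_path)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("io", exc) from exc
    excl = iomod.apply_exclusions(clinical)
    log["exclusions"] = excl.excluded.to_dict(orient="records")
    general = excl.general

    phenotyped, thresholds = _run_gating(
        config, cells_p1_path, cells_p2_path, log,
        include_cases=excl.general_cases)

    densities, benign_densities, comparisons = _run_densities(
        config, phenotyped, geometry_path, general, log)
    spatial_summaries = _run_spatial(config, phenotyped, log)

    extra = None
    if lymphocyte_densities_path is not None:
        extra = pd.read_csv(lymphocyte_densities_path,
                            dtype={"case_id": str})
    signatures, hot = _run_signatures(config, densities, log,
                                      extra_densities=extra)
    hazards = _run_survival(config, densities, spatial_summaries,
                            signatures, hot, general, log)

    tables = {
        "phenotypes": phenotyped[["cell_id", "core_id", "case_id",
                                  "panel", "label"]],
        "densities": densities,
        "comparisons": comparisons,
        "spatial_summaries": spatial_summaries,
        "signatures": signatures,
        "hot_excluded": hot,
        "hazards": hazards,
    }
    if benign_densities is not None:
        tables["benign_densities"] = benign_densities

    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    with open(out / "thresholds.yaml", "w") as fh:
        yaml.safe_dump({p: {"thresholds": t.thresholds,
                            "provenance": t.provenance}
                        for p, t in thresholds.items()}, fh, sort_keys=True)
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)

    tables["thresholds"] = thresholds
    tables["run_log"] = log
    return tables
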