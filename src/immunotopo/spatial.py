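"""Nearest-neighbor distances and interaction-zone counts.

All spatial operations act within a single core (distances never cross
cores) on Euclidean centroid-to-centroid distances.  The interaction zone
is the closed disc of the configured radius (15 μm by default) around a
reference cell; a cell never matches or counts itself, identified by
``cell_id`` rather than by zero distance so coincident distinct cells
still interact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree, ConvexHull, QhullError

__all__ = [
    "nearest_distance",
    "interaction_counts",
    "per_case_nearest_summary",
    "per_case_interaction_summary",
    "distance_to_hull",
]


def nearest_distance(
    ref_xy: np.ndarray,
    target_xy: np.ndarray,
    ref_ids=None,
    target_ids=None,
) -> np.ndarray:
    """Distance from each reference point to its nearest target (μm).

    When identifiers are supplied, a reference cell that also appears in
    the target set is matched to the nearest *other* target; if no other
    target exists its distance is NaN.
    """
    ref_xy = np.asarray(ref_xy, dtype=float).reshape(-1, 2)
    target_xy = np.asarray(target_xy, dtype=float).reshape(-1, 2)
    if len(target_xy) == 0:
        raise ValueError("target set is empty; distances undefined")
    tree = cKDTree(target_xy)
    k = min(2, len(target_xy))
    dist, idx = tree.query(ref_xy, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    out = dist[:, 0].astype(float).copy()
    if ref_ids is not None and target_ids is not None:
        ref_ids = np.asarray(ref_ids)
        target_ids = np.asarray(target_ids)
        self_hit = target_ids[idx[:, 0]] == ref_ids
        if k > 1:
            out[self_hit] = dist[self_hit, 1]
        else:
            out[self_hit] = np.nan
        # KD-tree tie order is arbitrary: if the second neighbor is the
        # self cell at the same distance, the first is already a valid
        # other cell, so only the first-slot hit needs fixing.
    return out


def interaction_counts(
    ref_xy: np.ndarray,
    neighbor_xy: np.ndarray,
    radius: float,
    ref_ids=None,
    neighbor_ids=None,
) -> np.ndarray:
    """Number of neighbor cells within the closed disc of `radius` (μm).

    The boundary is inclusive (distance ≤ radius counts) and a cell never
    counts itself.  Zero neighbors is a valid count.
    """
    if not radius > 0:
        raise ValueError("radius must be > 0")
    ref_xy = np.asarray(ref_xy, dtype=float).reshape(-1, 2)
    neighbor_xy = np.asarray(neighbor_xy, dtype=float).reshape(-1, 2)
    if len(neighbor_xy) == 0:
        return np.zeros(len(ref_xy), dtype=int)
    tree = cKDTree(neighbor_xy)
    hits = tree.query_ball_point(ref_xy, r=radius)
    counts = np.array([len(h) for h in hits], dtype=int)
    if ref_ids is not None and neighbor_ids is not None:
        ref_ids = np.asarray(ref_ids)
        neighbor_ids = np.asarray(neighbor_ids)
        id_to_pos = {cid: i for i, cid in enumerate(neighbor_ids)}
        for i, (rid, h) in enumerate(zip(ref_ids, hits)):
            j = id_to_pos.get(rid)
            if j is not None and j in h:
                counts[i] -= 1
    return counts


def _per_core_frames(cells: pd.DataFrame, label: str):
    sub = cells[cells["label"] == label]
    return {cid: grp for cid, grp in sub.groupby("core_id")}


def per_case_nearest_summary(
    cells: pd.DataFrame,
    ref_label: str,
    target_label: str,
) -> pd.DataFrame:
    """Mean nearest-neighbor distance per case (μm), pooling cells.

    For every reference cell the distance to the nearest target cell in
    the same core is computed; the case value is the mean over all
    reference cells pooled across the case's cores (cores with no target
    contribute no defined distances).  Cases lacking the reference class,
    or with no core containing both classes, are missing with a reason.
    """
    refs = _per_core_frames(cells, ref_label)
    targets = _per_core_frames(cells, target_label)
    core_case = cells.drop_duplicates("core_id").set_index("core_id")["case_id"]

    per_case: dict[str, list[np.ndarray]] = {}
    for core_id, ref in refs.items():
        tgt = targets.get(core_id)
        if tgt is None:
            continue
        d = nearest_distance(
            ref[["x_um", "y_um"]].to_numpy(), tgt[["x_um", "y_um"]].to_numpy(),
            ref_ids=ref["cell_id"].to_numpy(), target_ids=tgt["cell_id"].to_numpy(),
        )
        d = d[np.isfinite(d)]
        if d.size:
            per_case.setdefault(core_case[core_id], []).append(d)

    rows = []
    for case_id in sorted(cells["case_id"].unique()):
        if case_id in per_case:
            pooled = np.concatenate(per_case[case_id])
            rows.append({
                "case_id": case_id, "metric": "mean_nearest_distance",
                "reference": ref_label, "neighbor": target_label,
                "value": float(pooled.mean()), "n_reference": int(pooled.size),
                "missing_reason": "",
            })
        else:
            has_ref = any(core_case.get(c) == case_id for c in refs)
            reason = ("target class absent" if has_ref
                      else "reference class absent")
            rows.append({
                "case_id": case_id, "metric": "mean_nearest_distance",
                "reference": ref_label, "neighbor": target_label,
                "value": np.nan, "n_reference": 0, "missing_reason": reason,
            })
    return pd.DataFrame(rows)


def per_case_interaction_summary(
    cells: pd.DataFrame,
    ref_label: str,
    neighbor_label: str,
    radius: float = 15.0,
) -> pd.DataFrame:
    """Mean neighbor count within `radius` per reference cell, per case.

    Reference cells in cores lacking the neighbor class contribute a count
    of zero (a valid observation); the case is missing only when it has no
    reference cells at all.
    """
    refs = _per_core_frames(cells, ref_label)
    neighbors = _per_core_frames(cells, neighbor_label)
    core_case = cells.drop_duplicates("core_id").set_index("core_id")["case_id"]

    per_case: dict[str, list[np.ndarray]] = {}
    for core_id, ref in refs.items():
        nb = neighbors.get(core_id)
        if nb is None:
            c = np.zeros(len(ref), dtype=int)
        else:
            c = interaction_counts(
                ref[["x_um", "y_um"]].to_numpy(),
                nb[["x_um", "y_um"]].to_numpy(),
                radius,
                ref_ids=ref["cell_id"].to_numpy(),
                neighbor_ids=nb["cell_id"].to_numpy(),
            )
        per_case.setdefault(core_case[core_id], []).append(c)

    rows = []
    for case_id in sorted(cells["case_id"].unique()):
        if case_id in per_case:
            pooled = np.concatenate(per_case[case_id])
            rows.append({
                "case_id": case_id, "metric": "mean_interaction_count",
                "reference": ref_label, "neighbor": neighbor_label,
                "value": float(pooled.mean()), "n_reference": int(pooled.size),
                "missing_reason": "",
            })
        else:
            rows.append({
                "case_id": case_id, "metric": "mean_interaction_count",
                "reference": ref_label, "neighbor": neighbor_label,
                "value": np.nan, "n_reference": 0,
                "missing_reason": "reference class absent",
            })
    return pd.DataFrame(rows)


def distance_to_hull(core_cells: pd.DataFrame) -> np.ndarray:
    """Distance (μm) from each cell to the convex hull of its core's cells.

    Debug aid: TMA core edges truncate neighborhoods and no edge correction
    is applied, so users may wish to filter cells close to the boundary.
    """
    xy = core_cells[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(xy) < 3:
        return np.zeros(len(xy))
    try:
        hull = ConvexHull(xy)
    except QhullError:
        return np.zeros(len(xy))
    # hull.equations: a·x + b ≤ 0 inside; distance = -(a·x + b) / |a|.
    a = hull.equations[:, :2]
    b = hull.equations[:, 2]
    d = -(xy @ a.T + b) / np.linalg.norm(a, axis=1)
    return d.min(axis=1)
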