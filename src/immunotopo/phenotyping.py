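"""Marker thresholding and combinatorial phenotype gating.

Each multiplex panel measures six markers per cell. A cell is called
positive for a marker when its intensity strictly exceeds a per-marker
threshold learned from a random subset of training cores, and the
combination of positive/negative calls maps every cell to exactly one
phenotype class (or ``other``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "PANEL_MARKERS",
    "PHENOTYPE_SIGNATURES",
    "IMMUNE_CLASSES",
    "PhenotypeRule",
    "MarkerThresholds",
    "phenotype_rules",
    "derive_thresholds",
    "call_markers",
    "assign_phenotypes",
]

#: Marker set measured by each panel (order fixed for reproducibility).
PANEL_MARKERS: dict[str, tuple[str, ...]] = {
    "P1": ("CD3", "NKp46", "CD56", "CD68", "CD163", "CK"),
    "P2": ("CD1a", "CD208", "CD123", "CD15", "CD68", "CK"),
}

#: Canonical marker signature of each phenotype class: the set of markers a
#: prototypical cell of that class expresses; all other panel markers are
#: negative.  The synthetic-data generator draws intensities from these
#: signatures, so generator and gater share a single source of truth.
PHENOTYPE_SIGNATURES: dict[str, dict[str, frozenset[str]]] = {
    "P1": {
        "cancer": frozenset({"CK"}),
        "CD68_macrophage": frozenset({"CD68"}),
        "CD163_myeloid": frozenset({"CD163"}),
        "CD68_CD163_macrophage": frozenset({"CD68", "CD163"}),
        "NK": frozenset({"CD56", "NKp46"}),
        "CD56_NKT": frozenset({"CD3", "CD56"}),
        "NKp46_NKT": frozenset({"CD3", "NKp46"}),
        "CD56_NKp46_NKT": frozenset({"CD3", "CD56", "NKp46"}),
        "T_cell": frozenset({"CD3"}),
        "other": frozenset(),
    },
    "P2": {
        "cancer": frozenset({"CK"}),
        "iDC": frozenset({"CD1a"}),
        "mDC": frozenset({"CD208"}),
        "pDC": frozenset({"CD123"}),
        "CD1a_CD15_granulocyte": frozenset({"CD1a", "CD15"}),
        "CD208_CD15_granulocyte": frozenset({"CD208", "CD15"}),
        "CD123_CD15_granulocyte": frozenset({"CD123", "CD15"}),
        "other": frozenset(),
    },
}

#: Immune classes (everything but cancer / other) per panel.
IMMUNE_CLASSES: dict[str, tuple[str, ...]] = {
    panel: tuple(c for c in sigs if c not in ("cancer", "other"))
    for panel, sigs in PHENOTYPE_SIGNATURES.items()
}


@dataclass(frozen=True)
class PhenotypeRule:
    """A named combinatorial gate within one panel."""

    name: str
    panel: str
    positive: frozenset[str]
    negative: frozenset[str]

    def __post_init__(self) -> None:
        if self.positive & self.negative:
            raise ValueError(f"rule {self.name}: positive/negative overlap")


def phenotype_rules(panel: str) -> list[PhenotypeRule]:
    """Full-signature gating rules for a panel.

    Each rule requires its signature markers positive and every other panel
    marker negative, which makes the rules pairwise mutually exclusive.
    """
    markers = set(PANEL_MARKERS[panel])
    rules = []
    for name, pos in PHENOTYPE_SIGNATURES[panel].items():
        if name == "other":
            continue
        rules.append(
            PhenotypeRule(name=name, panel=panel, positive=pos,
                          negative=frozenset(markers - pos))
        )
    return rules


@dataclass
class MarkerThresholds:
    """Per-marker positivity thresholds with training provenance."""

    panel: str
    thresholds: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(PANEL_MARKERS[self.panel]) - set(self.thresholds)
        if missing:
            raise ValueError(f"thresholds missing markers: {sorted(missing)}")
        for m, t in self.thresholds.items():
            if not t > 0:
                raise ValueError(f"threshold for {m} must be > 0, got {t}")


# Gaussian-mixture components whose log-space means are closer than this are
# treated as effectively unimodal and routed to the percentile fallback.
_MIN_MODE_SEPARATION = 0.5
_FALLBACK_QUANTILE = 0.95


def derive_thresholds(
    cells: pd.DataFrame,
    panel: str,
    training_fraction: float = 0.25,
    seed: int = 0,
) -> MarkerThresholds:
    """Learn per-marker positivity thresholds from a random subset of cores.

    For each marker a two-component Gaussian mixture is fitted to
    ``log(intensity + 1)`` of the training cells; the threshold is the
    intensity at which the posterior probability of the high-mean component
    crosses 0.5.  Markers whose two components are closer than 0.5 log-units
    fall back to the 95th percentile of training intensities and are flagged
    in the provenance.

    Parameters
    ----------
    cells
        Cell table with ``core_id`` and ``int_<MARKER>`` columns for `panel`.
    panel
        ``"P1"`` or ``"P2"``.
    training_fraction
        Fraction of cores (at least one) used for training.
    seed
        Seed for core selection and mixture initialisation.
    """
    if not 0 < training_fraction <= 1:
        raise ValueError("training_fraction must be in (0, 1]")
    cores = np.sort(cells["core_id"].unique())
    if cores.size == 0:
        raise ValueError("no cores available for threshold training")
    rng = np.random.default_rng(seed)
    n_train = max(1, int(round(training_fraction * cores.size)))
    train_cores = np.sort(rng.choice(cores, size=n_train, replace=False))
    train = cells[cells["core_id"].isin(train_cores)]
    if len(train) < 50:
        raise ValueError(
            f"training set has {len(train)} cells; at least 50 required"
        )

    thresholds: dict[str, float] = {}
    methods: dict[str, str] = {}
    for marker in PANEL_MARKERS[panel]:
        x = train[f"int_{marker}"].to_numpy(dtype=float)
        z = np.log1p(x)
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            random_state=int(seed) % (2**31),
            n_init=3,
        ).fit(z.reshape(-1, 1))
        means = gm.means_.ravel()
        lo, hi = int(np.argmin(means)), int(np.argmax(means))
        if means[hi] - means[lo] < _MIN_MODE_SEPARATION:
            thresholds[marker] = float(np.quantile(x, _FALLBACK_QUANTILE))
            methods[marker] = "percentile_fallback"
            continue
        thr = _posterior_crossing(gm, hi, means[lo], means[hi])
        if thr is None:
            thresholds[marker] = float(np.quantile(x, _FALLBACK_QUANTILE))
            methods[marker] = "percentile_fallback"
        else:
            thresholds[marker] = float(np.expm1(thr))
            methods[marker] = "gmm_posterior_crossing"

    return MarkerThresholds(
        panel=panel,
        thresholds=thresholds,
        provenance={
            "method": methods,
            "training_cores": [str(c) for c in train_cores],
            "training_fraction": training_fraction,
            "n_training_cells": int(len(train)),
            "seed": int(seed),
        },
    )


def _posterior_crossing(gm: GaussianMixture, hi: int, z_lo: float,
                        z_hi: float) -> float | None:
    """Log-intensity where the high component's posterior crosses 0.5.

    Grid scan between the component means followed by bisection refinement.
    Returns None when the posterior never crosses within the bracket.
    """

    def p_hi(z: np.ndarray) -> np.ndarray:
        return gm.predict_proba(np.asarray(z, dtype=float).reshape(-1, 1))[:, hi]

    grid = np.linspace(z_lo, z_hi, 2049)
    post = p_hi(grid)
    above = post >= 0.5
    if not above.any() or above[0]:
        return None
    i = int(np.argmax(above))  # first index at/above 0.5
    a, b = grid[i - 1], grid[i]
    for _ in range(60):
        m = 0.5 * (a + b)
        if p_hi(np.array([m]))[0] >= 0.5:
            b = m
        else:
            a = m
    return 0.5 * (a + b)


def call_markers(cells: pd.DataFrame, thresholds: MarkerThresholds) -> pd.DataFrame:
    """Boolean positivity call per cell and marker.

    A cell is positive iff intensity strictly exceeds the marker threshold;
    intensity equal to the threshold is negative.
    """
    markers = PANEL_MARKERS[thresholds.panel]
    missing = [m for m in markers if m not in thresholds.thresholds]
    if missing:
        raise ValueError(f"thresholds missing markers: {missing}")
    calls = pd.DataFrame(index=cells.index)
    for m in markers:
        calls[m] = cells[f"int_{m}"].to_numpy(dtype=float) > thresholds.thresholds[m]
    return calls


def assign_phenotypes(calls: pd.DataFrame, panel: str) -> pd.Series:
    """Map marker calls to exactly one phenotype label per cell.

    The gate is a priority cascade.  Panel 1: cytokeratin positivity marks
    cancer and overrides all immune gates; CD3-positive cells branch into the
    NKT subtypes (made disjoint by requiring the complementary NK marker
    negative) or plain T cells; CD3-negative cells are NK if CD56+NKp46+,
    otherwise macrophage/myeloid classes by CD68/CD163.  Panel 2: cancer by
    CK; CD68 is an exclusion marker (CD68+ non-cancer cells become
    ``other``); remaining cells must express exactly one of CD1a/CD208/CD123
    to be a dendritic-cell class (CD15-) or granulocyte class (CD15+).
    """
    for m in PANEL_MARKERS[panel]:
        if m not in calls.columns:
            raise ValueError(f"marker calls missing column {m}")

    if panel == "P1":
        cd3, nkp46, cd56 = calls["CD3"], calls["NKp46"], calls["CD56"]
        cd68, cd163, ck = calls["CD68"], calls["CD163"], calls["CK"]
        conditions = [
            ck,
            cd3 & cd56 & nkp46,
            cd3 & cd56,
            cd3 & nkp46,
            cd3 & ~cd68 & ~cd163,
            ~cd3 & cd56 & nkp46,
            ~cd3 & cd68 & cd163,
            ~cd3 & cd68,
            ~cd3 & cd163,
        ]
        labels = [
            "cancer",
            "CD56_NKp46_NKT",
            "CD56_NKT",
            "NKp46_NKT",
            "T_cell",
            "NK",
            "CD68_CD163_macrophage",
            "CD68_macrophage",
            "CD163_myeloid",
        ]
    elif panel == "P2":
        cd1a, cd208, cd123 = calls["CD1a"], calls["CD208"], calls["CD123"]
        cd15, cd68, ck = calls["CD15"], calls["CD68"], calls["CK"]
        one_dc = (cd1a.astype(int) + cd208.astype(int) + cd123.astype(int)) == 1
        conditions = [
            ck,
            cd68,  # exclusion marker -> other
            cd15 & one_dc & cd1a,
            cd15 & one_dc & cd208,
            cd15 & one_dc & cd123,
            ~cd15 & one_dc & cd1a,
            ~cd15 & one_dc & cd208,
            ~cd15 & one_dc & cd123,
        ]
        labels = [
            "cancer",
            "other",
            "CD1a_CD15_granulocyte",
            "CD208_CD15_granulocyte",
            "CD123_CD15_granulocyte",
            "iDC",
            "mDC",
            "pDC",
        ]
    else:
        raise ValueError(f"unknown panel {panel!r}")

    out = np.select(conditions, labels, default="other")
    return pd.Series(out, index=calls.index, name="label")
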