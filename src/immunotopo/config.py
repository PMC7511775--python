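"""Run configuration and deterministic per-stage seeding."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "stage_seed", "stage_rng"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable 31-bit child seed for a named pipeline stage.

    All randomness in a run flows from one top-level seed; each stage gets
    an independent stream keyed by its name so adding or reordering stages
    does not perturb the others.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed), int(tag)])
    return int(ss.generate_state(1)[0] % (2**31))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))


@dataclass
class RunConfig:
    """Tunable parameters of a pipeline run.

    Attributes
    ----------
    interaction_radius
        Radius (μm) of the closed interaction zone around a reference cell.
    followup_cap
        Follow-up cap in months for survival analyses; deaths after the cap
        are recoded as censored at the cap.
    threshold_method
        Positivity-threshold method (``"gmm"`` only; fallback handled
        internally).
    threshold_training_fraction
        Fraction of cores used to train marker thresholds.
    rng_seed
        Top-level seed; every stage derives its own stream from it.
    cluster_k
        Number of hierarchical clusters per feature view.
    ratio_pseudocount
        Pseudocount ε (cells/mm²) in the tumor:stroma infiltration ratio.
    min_prevalence
        Minimum fraction of cases in which a phenotype must be present for
        it to enter clustering / ratio classification.
    """

    interaction_radius: float = 15.0
    followup_cap: float = 60.0
    threshold_method: str = "gmm"
    threshold_training_fraction: float = 0.25
    rng_seed: int = 0
    cluster_k: dict = field(
        default_factory=lambda: {"total": 5, "stroma": 5, "tumor": 4, "combined": 4}
    )
    ratio_pseudocount: float = 0.1
    min_prevalence: float = 0.05
    adjust_pvalues: bool = False  # optional Benjamini-Hochberg on comparisons

    def __post_init__(self) -> None:
        if not self.interaction_radius > 0:
            raise ValueError("interaction_radius must be > 0")
        if not self.followup_cap > 0:
            raise ValueError("followup_cap must be > 0")
        if not 0 < self.threshold_training_fraction <= 1:
            raise ValueError("threshold_training_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.rng_seed, stage)
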