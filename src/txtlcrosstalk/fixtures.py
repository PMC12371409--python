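"""Synthetic experimental-style dataset generation.

Emulates the structure of the plate-reader crosstalk dataset — tidy
time-course tables over the condition grid (5-min sampling over 3 h, 3
technical replicates) — by simulating the model at a known generating
parameterization and perturbing the readout with multiplicative Gaussian
noise.  The generating parameters are returned as metadata, so recovery
tests have ground truth.

What this emulates: the grid structure, sampling schedule, replicate noise
scale.  What it does not: lysate batch-to-batch variability, pipetting
covariance between wells, autofluorescence background drift — synthetic
fixtures are idealisations of real data.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .experiments import Condition, run_grid
from .parameters import ParameterSet
from .simulate import readout_at
from .units import ResourceSpec, ToxinConfig, TranscriptionUnitSpec

__all__ = ["FixtureSpec", "generate_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Generating parameters + noise model for a synthetic dataset."""

    params: ParameterSet
    cv: float = 0.05  # multiplicative Gaussian coefficient of variation
    replicates: int = 3
    t_end: float = 3 * 3600.0
    t_step: float = 300.0
    seed: int = 0
    toxin_variant: str = "TL_TL"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def generate_fixture(
    spec: FixtureSpec,
    conditions: Iterable[Condition],
    units: list[TranscriptionUnitSpec],
    resources: ResourceSpec | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the conditions and emit a noisy tidy table plus metadata.

    Returns ``(table, metadata)`` where the table has columns condition_id,
    replicate, time_s, value (nM) and metadata records the generating
    parameters, noise model and seed (the ground truth for recovery tests).
    """
    conditions = list(conditions)
    p = spec.params
    toxin = ToxinConfig(
        spec.toxin_variant,
        b=p.get("b", 0.0),
        k_toxin=p.get("k_toxin", 0.0),
        toxin_threshold=p.get("toxin_threshold", 0.0),
    )
    grid = run_grid(
        units, p, conditions, resources=resources, toxin=toxin,
        t_end=spec.t_end, t_step=spec.t_step,
    )
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cond in conditions:
        tc = grid[cond]
        clean = tc.readouts[cond.reporter_unit]
        for rep in range(1, spec.replicates + 1):
            noise = rng.normal(0.0, spec.cv, size=clean.shape) if spec.cv > 0 else 0.0
            rows.append(
                pd.DataFrame(
                    {
                        "condition_id": cond.condition_id,
                        "replicate": rep,
                        "time_s": tc.times,
                        "value": clean * (1.0 + noise),
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    metadata = {
        "generating_parameters": p.as_dict(),
        "noise_cv": spec.cv,
        "replicates": spec.replicates,
        "t_end_s": spec.t_end,
        "t_step_s": spec.t_step,
        "seed": spec.seed,
        "toxin_variant": spec.toxin_variant,
        "n_conditions": len(conditions),
    }
    return table, metadata
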