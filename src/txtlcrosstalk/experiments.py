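"""Condition grids, dose composition, grid simulation and crosstalk ratios.

The experimental design being emulated: a reporter plasmid (protein-level
sfGFP or RNA-level 3WJdB aptamer) under one of four promoters, dosed at seven
concentrations {0.5, 1, 2.5, 5, 10, 15, 30} nM, in four plasmid combinations —
reporter only, or reporter plus 10 nM of an "empty" vector carrying (i) no
promoter, (ii) a strong T7 promoter, or (iii) a strong sigma-70 promoter.
Every physical plasmid additionally carries the kanamycin-resistance marker
(kanR), which is itself expressed; the pooled kanR unit is therefore dosed at
the sum of all plasmid concentrations present.

The crosstalk ratio of a condition is the 3-h reporter readout with the added
plasmid divided by the same-concentration reporter-only readout; > 1 is
positive crosstalk (nuclease distraction), < 1 negative (resource
competition / toxin).
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import ReactionNetwork, build_network
from .simulate import DoseSchedule, SimulationError, TimeCourse, readout_at, simulate
from .units import ResourceSpec, ToxinConfig, TranscriptionUnitSpec

__all__ = [
    "Condition",
    "REPORTER_CONCS",
    "COMBOS",
    "SFGFP_PROMOTERS",
    "APTAMER_PROMOTERS",
    "enumerate_conditions",
    "compose_doses",
    "crosstalk_ratio",
    "run_grid",
    "GridResult",
    "crosstalk_table",
]

REPORTER_CONCS = (0.5, 1.0, 2.5, 5.0, 10.0, 15.0, 30.0)
COMBOS = ("reporter_only", "empty_no_promoter", "empty_T7_strong", "empty_sig70_strong")
SFGFP_PROMOTERS = ("T7_strong", "T7_weak", "sig70_strong", "sig70_weak")
APTAMER_PROMOTERS = ("T7_strong", "T7_weak", "sig70_strong")
DEFAULT_EMPTY_CONC = 10.0
#: crosstalk ratios are evaluated at the 3-h timepoint
T_RATIO = 3 * 3600.0


@dataclass(frozen=True)
class Condition:
    """One cell of the reporter x concentration x plasmid-combination grid."""

    reporter: str  # "sfGFP" | "aptamer3WJdB"
    promoter: str
    reporter_conc: float
    combo: str
    empty_conc: float = DEFAULT_EMPTY_CONC

    def __post_init__(self) -> None:
        if self.reporter not in ("sfGFP", "aptamer3WJdB"):
            raise ValueError(f"unknown reporter {self.reporter!r}")
        if self.combo not in COMBOS:
            raise ValueError(f"unknown combo {self.combo!r}")
        if self.reporter == "aptamer3WJdB" and self.promoter == "sig70_weak":
            raise ValueError("aptamer reporter on sig70_weak is below the noise floor")
        if self.reporter_conc <= 0 or self.empty_conc < 0:
            raise ValueError("concentrations must be positive")

    @property
    def reporter_unit(self) -> str:
        stem = "sfGFP" if self.reporter == "sfGFP" else "aptamer"
        return f"{stem}_{self.promoter}"

    @property
    def condition_id(self) -> str:
        return f"{self.reporter}|{self.promoter}|{self.reporter_conc:g}|{self.combo}"

    @classmethod
    def from_id(cls, condition_id: str, empty_conc: float = DEFAULT_EMPTY_CONC) -> "Condition":
        reporter, promoter, conc, combo = condition_id.split("|")
        return cls(reporter, promoter, float(conc), combo, empty_conc)

    @property
    def baseline(self) -> "Condition":
        """The same-concentration reporter-only condition."""
        return Condition(self.reporter, self.promoter, self.reporter_conc, "reporter_only", self.empty_conc)


def enumerate_conditions(
    reporter: str = "sfGFP",
    promoters: Iterable[str] | None = None,
    concs: Iterable[float] = REPORTER_CONCS,
    combos: Iterable[str] = COMBOS,
    empty_conc: float = DEFAULT_EMPTY_CONC,
) -> list[Condition]:
    """Full condition cross-product, ordered promoter > concentration > combo.

    sfGFP: 4 promoters x 7 concentrations x 4 combos = 112 conditions;
    the aptamer drops sigma-70 weak, 3 x 7 x 4 = 84.
    """
    if promoters is None:
        promoters = SFGFP_PROMOTERS if reporter == "sfGFP" else APTAMER_PROMOTERS
    return [
        Condition(reporter, p, c, combo, empty_conc)
        for p in promoters
        for c in concs
        for combo in combos
    ]


def compose_doses(condition: Condition) -> DoseSchedule:
    """Per-unit DNA doses for a condition.

    The reporter unit gets ``reporter_conc``; promoter-bearing empty vectors
    get ``empty_conc``; the pooled kanR marker gets the SUM of all physical
    plasmid concentrations — including the promoterless empty vector, which
    contributes only its kanR cassette.
    """
    doses: dict[str, float] = {condition.reporter_unit: condition.reporter_conc}
    kanr = condition.reporter_conc
    if condition.combo != "reporter_only":
        kanr += condition.empty_conc
        if condition.combo == "empty_T7_strong":
            doses["empty_T7_strong"] = condition.empty_conc
        elif condition.combo == "empty_sig70_strong":
            doses["empty_sig70_strong"] = condition.empty_conc
        # empty_no_promoter: no transcribable empty unit, kanR burden only
    doses["kanR"] = kanr
    return DoseSchedule(dna_doses=doses)


def crosstalk_ratio(
    tc_with: TimeCourse,
    tc_without: TimeCourse,
    readout: str,
    t: float = T_RATIO,
) -> float:
    """readout(with added plasmid, t) / readout(reporter only, t).

    Returns NaN (flagged undefined) when the baseline readout is zero or
    negative; downstream surrogate terms exclude undefined cells.
    """
    baseline = readout_at(tc_without, readout, t)
    if baseline <= 0:
        return float("nan")
    return readout_at(tc_with, readout, t) / baseline


@dataclass
class GridResult:
    """Time courses for a set of conditions, keyed by condition id."""

    timecourses: dict[str, TimeCourse]
    failures: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, cond: "Condition | str") -> TimeCourse:
        key = cond.condition_id if isinstance(cond, Condition) else cond
        return self.timecourses[key]

    def __len__(self) -> int:
        return len(self.timecourses)

    def terminal_readout(self, condition: Condition, t: float = T_RATIO) -> float:
        tc = self[condition]
        return readout_at(tc, condition.reporter_unit, t)

    def to_frame(self) -> pd.DataFrame:
        if not self.timecourses:
            return pd.DataFrame(
                columns=["condition_id", "species_or_readout", "time_s", "value_nM"]
            )
        return pd.concat([tc.to_frame() for tc in self.timecourses.values()], ignore_index=True)


def _pruned_network(
    units: list[TranscriptionUnitSpec],
    dosed_ids: frozenset[str],
    resources: ResourceSpec,
    toxin: ToxinConfig,
    cache: dict,
) -> ReactionNetwork:
    net = cache.get(dosed_ids)
    if net is None:
        net = build_network([u for u in units if u.id in dosed_ids], resources, toxin)
        cache[dosed_ids] = net
    return net


def run_grid(
    units: list[TranscriptionUnitSpec],
    params: Mapping[str, float] | None,
    conditions: Iterable[Condition],
    resources: ResourceSpec | None = None,
    toxin: ToxinConfig | None = None,
    t_end: float = T_RATIO,
    t_step: float = 300.0,
    rtol: float = 1e-6,
    atol: float = 1e-12,
    prune: bool = True,
    n_jobs: int = 1,
    raise_on_failure: bool = True,
) -> GridResult:
    """Simulate one time course per condition.

    Undosed units carry exactly zero flux, so by default each condition is
    integrated on the subnetwork of its dosed units (identical trajectories,
    much faster).  Deterministic given parameters and tolerances, regardless
    of ``n_jobs``/scheduling.
    """
    resources = resources or ResourceSpec()
    toxin = toxin or ToxinConfig()
    conditions = list(conditions)
    full_net = build_network(units, resources, toxin)
    cache: dict = {}

    def _one(cond: Condition):
        doses = compose_doses(cond)
        if prune:
            net = _pruned_network(
                units, frozenset(doses.dna_doses), resources, toxin, cache
            )
        else:
            net = full_net
        try:
            tc = simulate(
                net, params, doses, t_end=t_end, t_step=t_step, rtol=rtol, atol=atol,
                condition_id=cond.condition_id,
            )
            return cond.condition_id, tc, None
        except SimulationError as exc:
            return cond.condition_id, None, str(exc)

    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(_one)(c) for c in conditions)
    else:
        results = [_one(c) for c in conditions]

    out = GridResult(timecourses={})
    for cid, tc, err in results:
        if err is not None:
            if raise_on_failure:
                raise SimulationError(f"{cid}: {err}")
            out.failures[cid] = err
        else:
            out.timecourses[cid] = tc
    return out


def crosstalk_table(
    grid: GridResult,
    conditions: Iterable[Condition],
    t: float = T_RATIO,
) -> pd.DataFrame:
    """Crosstalk ratios for every added-plasmid condition against its baseline.

    Columns: promoter, reporter_conc_nM, combo, ratio.  A NaN ratio marks an
    undefined cell (zero/negative baseline or a failed simulation).
    """
    rows = []
    for cond in conditions:
        if cond.combo == "reporter_only":
            continue
        try:
            tc_with = grid[cond]
            tc_base = grid[cond.baseline]
            ratio = crosstalk_ratio(tc_with, tc_base, cond.reporter_unit, t)
        except KeyError:
            ratio = float("nan")
        rows.append(
            {
                "promoter": cond.promoter,
                "reporter_conc_nM": cond.reporter_conc,
                "combo": cond.combo,
                "ratio": ratio,
            }
        )
    return pd.DataFrame(rows, columns=["promoter", "reporter_conc_nM", "combo", "ratio"])
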