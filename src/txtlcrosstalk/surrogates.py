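"""Surrogate terms encoding qualitative crosstalk phenotypes, and their criteria.

Rather than fitting absolute expression levels, parameterizations are screened
for qualitative experimental trends.  Each trend is encoded as a scalar
*surrogate term*, defined so that a more negative value means better agreement
with the desired phenotype, and compared against a goal threshold (criterion
satisfied iff term <= goal, inclusive).

Terms
-----
baseline penalty (per promoter)
    sign * log10 |terminal readout at 30 nM - best terminal readout among the
    six lower concentrations|.  For strong promoters the sign is +1 when the
    30 nM condition is the maximum (undesired: no high-dose decrease) and -1
    otherwise; for sigma-70 weak the rule is inverted (a monotone increase is
    the desired phenotype there).  |diff| is floored at 1e-12 nM.
positive crosstalk term (per promoter)
    1 - max crosstalk ratio over the 0.5, 1 and 2.5 nM reporter doses (all
    added-plasmid combos); negative when positive crosstalk is present.
negative crosstalk term (per promoter)
    min crosstalk ratio over the 5, 10, 15 and 30 nM doses, minus 1.
large positive crosstalk term
    max positive ratio of the strong promoters minus that of sigma-70 weak
    (negative when the weak promoter shows the larger positive crosstalk).
deviation term
    mean |simulated - reference| crosstalk ratio over all defined cells
    (requires a reference ratio table).
residual mRNA term
    mean over reporter-only conditions of log10(total mRNA at t_end / peak
    total mRNA), floored — very negative when RNA rises then decays to zero.

Default goals: -1e-4 for the baseline penalties and -0.05 for the crosstalk
terms; goals for the remaining terms are population medians supplied by the
screening layer.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .experiments import (
    COMBOS,
    Condition,
    GridResult,
    REPORTER_CONCS,
    SFGFP_PROMOTERS,
    crosstalk_table,
)

__all__ = [
    "SurrogateReport",
    "LOG_FLOOR",
    "DEFAULT_GOALS",
    "STRONG_PROMOTERS",
    "baseline_penalty",
    "positive_crosstalk_term",
    "negative_crosstalk_term",
    "auxiliary_terms",
    "evaluate_criteria",
    "compute_report",
    "scale_terms",
]

#: absolute differences/ratios are floored at this value before taking log10
LOG_FLOOR = 1e-12

STRONG_PROMOTERS = ("T7_strong", "T7_weak", "sig70_strong")
WEAK_PROMOTER = "sig70_weak"
LOW_CONCS = (0.5, 1.0, 2.5)
HIGH_CONCS = (5.0, 10.0, 15.0, 30.0)

#: default goal registry; deviation / large-positive / residual goals are
#: population medians and must be supplied by the caller (screening layer)
DEFAULT_GOALS: dict[str, float] = {
    "baseline_strong": -1e-4,
    "baseline_sig70_weak": -1e-4,
    "crosstalk_T7_strong": -0.05,
    "crosstalk_T7_weak": -0.05,
    "crosstalk_sig70_strong": -0.05,
    "crosstalk_sig70_weak": -0.05,
}

#: the criteria encoding the two key experimental trends (high-dose baseline
#: decrease; positive-to-negative crosstalk transition)
KEY_TREND_CRITERIA = (
    "baseline_strong",
    "baseline_sig70_weak",
    "crosstalk_T7_strong",
    "crosstalk_T7_weak",
    "crosstalk_sig70_strong",
    "crosstalk_sig70_weak",
)

ALL_CRITERIA = KEY_TREND_CRITERIA + ("large_positive", "deviation", "residual_mrna")


@dataclass
class SurrogateReport:
    """Per-parameterization surrogate term values and criteria outcomes."""

    terms: dict[str, float]
    criteria: dict[str, bool] = field(default_factory=dict)
    n_satisfied: int = 0

    @property
    def key_trend_complete(self) -> bool:
        """True when the baseline and all four promoter crosstalk criteria hold."""
        return all(self.criteria.get(c, False) for c in KEY_TREND_CRITERIA)

    def to_dict(self) -> dict:
        return {
            "terms": dict(self.terms),
            "criteria": dict(self.criteria),
            "n_satisfied": self.n_satisfied,
            "key_trend_complete": self.key_trend_complete,
        }


def _floored_log10(x: float) -> float:
    return math.log10(max(abs(x), LOG_FLOOR))


def baseline_penalty(terminal_readouts: Mapping[float, float], promoter: str) -> float:
    """Signed log-magnitude of the 30 nM vs best-lower-dose difference.

    ``terminal_readouts`` maps reporter concentration (nM) to the terminal
    readout; all seven grid concentrations must be present.
    """
    missing = [c for c in REPORTER_CONCS if c not in terminal_readouts]
    if missing:
        raise KeyError(f"missing terminal readouts at {missing} nM")
    r30 = terminal_readouts[30.0]
    best_lower = max(terminal_readouts[c] for c in REPORTER_CONCS if c != 30.0)
    thirty_is_max = r30 >= best_lower
    if promoter == WEAK_PROMOTER:
        s = -1.0 if thirty_is_max else 1.0
    else:
        s = 1.0 if thirty_is_max else -1.0
    return s * _floored_log10(r30 - best_lower)


def _ratio_slice(ratios: pd.DataFrame, promoter: str, concs: Iterable[float]) -> np.ndarray:
    sel = ratios[
        (ratios["promoter"] == promoter) & (ratios["reporter_conc_nM"].isin(list(concs)))
    ]["ratio"].to_numpy(dtype=float)
    return sel[np.isfinite(sel)]


def positive_crosstalk_term(ratios: pd.DataFrame, promoter: str) -> float:
    """1 minus the max crosstalk ratio at the low (0.5/1/2.5 nM) doses."""
    vals = _ratio_slice(ratios, promoter, LOW_CONCS)
    if vals.size == 0:
        raise ValueError(f"no defined crosstalk ratios for {promoter} at {LOW_CONCS}")
    return 1.0 - float(vals.max())


def negative_crosstalk_term(ratios: pd.DataFrame, promoter: str) -> float:
    """Min crosstalk ratio at the high (5/10/15/30 nM) doses, minus 1."""
    vals = _ratio_slice(ratios, promoter, HIGH_CONCS)
    if vals.size == 0:
        raise ValueError(f"no defined crosstalk ratios for {promoter} at {HIGH_CONCS}")
    return float(vals.min()) - 1.0


def auxiliary_terms(
    grid: GridResult,
    conditions: Iterable[Condition],
    ratios: pd.DataFrame,
    reference_ratios: pd.DataFrame | None = None,
    t_end: float | None = None,
) -> dict[str, float]:
    """large_positive, deviation (needs a reference table) and residual_mrna."""
    conditions = list(conditions)
    out: dict[str, float] = {}
    strong_vals = [
        float(np.max(_ratio_slice(ratios, p, REPORTER_CONCS)))
        for p in STRONG_PROMOTERS
        if _ratio_slice(ratios, p, REPORTER_CONCS).size
    ]
    weak_vals = _ratio_slice(ratios, WEAK_PROMOTER, REPORTER_CONCS)
    if strong_vals and weak_vals.size:
        out["large_positive"] = max(strong_vals) - float(weak_vals.max())
    else:
        out["large_positive"] = float("nan")

    if reference_ratios is not None:
        merged = ratios.merge(
            reference_ratios,
            on=["promoter", "reporter_conc_nM", "combo"],
            suffixes=("_sim", "_ref"),
        )
        diffs = (merged["ratio_sim"] - merged["ratio_ref"]).abs()
        diffs = diffs[np.isfinite(diffs)]
        out["deviation"] = float(diffs.mean()) if len(diffs) else float("nan")

    logs = []
    for cond in conditions:
        if cond.combo != "reporter_only":
            continue
        try:
            tc = grid[cond]
        except KeyError:
            continue
        series = tc.readouts["total_mRNA"]
        peak = float(series.max())
        end = float(series[-1])
        if peak <= 0:
            continue
        logs.append(_floored_log10(end / peak) if end > 0 else math.log10(LOG_FLOOR))
    out["residual_mrna"] = float(np.mean(logs)) if logs else float("nan")
    return out


def evaluate_criteria(
    terms: Mapping[str, float], goals: Mapping[str, float]
) -> tuple[dict[str, bool], int]:
    """Inclusive term <= goal comparison for every goal-registered criterion."""
    criteria: dict[str, bool] = {}
    for name, goal in goals.items():
        if name not in terms:
            raise KeyError(f"goal {name!r} has no matching term")
        val = terms[name]
        criteria[name] = bool(np.isfinite(val) and val <= goal)
    return criteria, sum(criteria.values())


def compute_report(
    grid: GridResult,
    conditions: Iterable[Condition],
    goals: Mapping[str, float] | None = None,
    reference_ratios: pd.DataFrame | None = None,
    t: float | None = None,
) -> SurrogateReport:
    """Full surrogate evaluation of a simulated reporter grid.

    Produces per-promoter baseline penalties and crosstalk terms, the
    aggregate criteria registry (strong-promoter baselines are aggregated
    worst-case; each promoter crosstalk criterion requires BOTH its positive
    and negative term to meet the goal) and, where computable, the auxiliary
    terms.
    """
    conditions = list(conditions)
    goals = dict(goals) if goals is not None else dict(DEFAULT_GOALS)
    ratios = crosstalk_table(grid, conditions, t=t) if t else crosstalk_table(grid, conditions)
    promoters = sorted({c.promoter for c in conditions})

    terms: dict[str, float] = {}
    for prom in promoters:
        readouts = {}
        for conc in REPORTER_CONCS:
            cond = Condition(
                conditions[0].reporter, prom, conc, "reporter_only", conditions[0].empty_conc
            )
            try:
                readouts[conc] = grid.terminal_readout(cond, t or 3 * 3600.0)
            except KeyError:
                pass
        if len(readouts) == len(REPORTER_CONCS):
            terms[f"baseline_{prom}"] = baseline_penalty(readouts, prom)
        terms[f"positive_crosstalk_{prom}"] = positive_crosstalk_term(ratios, prom)
        terms[f"negative_crosstalk_{prom}"] = negative_crosstalk_term(ratios, prom)

    # aggregate registry terms
    strong_baselines = [terms[f"baseline_{p}"] for p in STRONG_PROMOTERS if f"baseline_{p}" in terms]
    if strong_baselines:
        terms["baseline_strong"] = max(strong_baselines)  # worst case
    if f"baseline_{WEAK_PROMOTER}" in terms:
        terms["baseline_sig70_weak"] = terms[f"baseline_{WEAK_PROMOTER}"]
    for prom in promoters:
        terms[f"crosstalk_{prom}"] = max(
            terms[f"positive_crosstalk_{prom}"], terms[f"negative_crosstalk_{prom}"]
        )
    terms.update(
        auxiliary_terms(grid, conditions, ratios, reference_ratios=reference_ratios)
    )

    usable_goals = {k: v for k, v in goals.items() if k in terms}
    criteria, n = evaluate_criteria(terms, usable_goals)
    return SurrogateReport(terms=terms, criteria=criteria, n_satisfied=n)


def scale_terms(values: np.ndarray | pd.DataFrame, limit: float = 15.0):
    """Affine map of each term's population range onto [-limit, +limit].

    Order-preserving per term; a term constant across the population maps to 0
    (with a warning).  Input rows are parameterizations, columns terms.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] < 2:
        raise ValueError("scaling requires a population of at least 2 parameterizations")
    lo = np.nanmin(arr, axis=0)
    hi = np.nanmax(arr, axis=0)
    span = hi - lo
    scaled = np.zeros_like(arr)
    for j in range(arr.shape[1]):
        if span[j] == 0 or not np.isfinite(span[j]):
            warnings.warn(f"term column {j} is constant across the population; scaled to 0")
            scaled[:, j] = 0.0
        else:
            scaled[:, j] = (arr[:, j] - lo[j]) / span[j] * (2 * limit) - limit
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(scaled, index=values.index, columns=values.columns)
    return scaled if np.asarray(values).ndim > 1 else scaled[:, 0]
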