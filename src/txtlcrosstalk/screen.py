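"""Log-space Latin hypercube sampling, biological filters, and screening.

The parameter space (~40 positive kinetic constants spanning several orders of
magnitude each) is explored with Latin hypercube sampling on log10-transformed
bounds, filtered by four biological plausibility heuristics, and each
surviving parameterization is scored by simulating the full reporter grid and
evaluating the surrogate criteria.
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .experiments import Condition, run_grid
from .parameters import ParameterBounds, ParameterSet
from .simulate import SimulationError
from .surrogates import (
    ALL_CRITERIA,
    DEFAULT_GOALS,
    SurrogateReport,
    compute_report,
    scale_terms,
)
from .units import ResourceSpec, ToxinConfig, TranscriptionUnitSpec

__all__ = [
    "lhs_sample",
    "heuristic_filter",
    "filter_population",
    "screen",
    "ScreenResult",
    "optimize_surrogate",
    "OptimizeResult",
]


def lhs_sample(bounds: ParameterBounds, n: int, seed: int) -> list[ParameterSet]:
    """n Latin-hypercube samples, stratified in log10 space per parameter.

    Each parameter's n samples fall exactly one per equal-width bin of its
    log-range; reproducible under ``seed``.  Parameters in ``bounds.fixed``
    are pinned to their fixed value.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names, lo, hi = bounds.log_arrays()
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    u = sampler.random(n)
    logs = lo + u * (hi - lo)
    out = []
    for row in logs:
        vals = {name: 10.0 ** x for name, x in zip(names, row)}
        vals.update(bounds.fixed)
        out.append(ParameterSet(vals))
    return out


def _kd(p: Mapping[str, float], kf: str, kr: str) -> float:
    return p[kr] / p[kf]


def heuristic_filter(p: Mapping[str, float]) -> bool:
    """The four biological plausibility constraints on a parameter set.

    (i)   T7 strong binds T7 RNAP more tightly than T7 weak;
    (ii)  sigma-70 weak binds native RNAP more weakly than sigma-70 strong
          and than T7 weak binds T7 RNAP;
    (iii) reporter mRNAs (sfGFP, aptamer) bind ribonuclease more weakly than
          kanR and empty-vector RNA (stabilising UTR structure);
    (iv)  the catalytic degradation constant of kanR/sfGFP/aptamer mRNA is
          lower than that of the (much shorter) empty-vector RNA.

    Affinity comparisons use Kd = kr/kf (smaller = stronger).  Raises KeyError
    if a referenced parameter is missing.
    """
    kd_t7s = _kd(p, "kf_tx_T7_strong", "kr_tx_T7_strong")
    kd_t7w = _kd(p, "kf_tx_T7_weak", "kr_tx_T7_weak")
    kd_s70s = _kd(p, "kf_tx_sig70_strong", "kr_tx_sig70_strong")
    kd_s70w = _kd(p, "kf_tx_sig70_weak", "kr_tx_sig70_weak")
    if not kd_t7s < kd_t7w:
        return False
    if not (kd_s70w > kd_s70s and kd_s70w > kd_t7w):
        return False
    kd_nuc = {c: _kd(p, f"kf_nuc_{c}", f"kr_nuc_{c}") for c in ("sfGFP", "aptamer", "kanR", "empty")}
    if not (
        kd_nuc["sfGFP"] > kd_nuc["kanR"]
        and kd_nuc["sfGFP"] > kd_nuc["empty"]
        and kd_nuc["aptamer"] > kd_nuc["kanR"]
        and kd_nuc["aptamer"] > kd_nuc["empty"]
    ):
        return False
    if not (
        p["k_deg_kanR"] < p["k_deg_empty"]
        and p["k_deg_sfGFP"] < p["k_deg_empty"]
        and p["k_deg_aptamer"] < p["k_deg_empty"]
    ):
        return False
    return True


def filter_population(population: Iterable[ParameterSet]) -> list[ParameterSet]:
    return [p for p in population if heuristic_filter(p)]


@dataclass
class ScreenResult:
    """Screening outcome: one row per parameter set, ranked."""

    table: pd.DataFrame  # parameters, terms, criteria, n_satisfied, rank
    reports: list[SurrogateReport | None]
    goals: dict[str, float]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def best(self) -> pd.Series:
        return self.table.sort_values("rank").iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def save_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"goals": self.goals, **self.metadata}, fh, indent=2, default=str)


def _toxin_from(params: Mapping[str, float], variant: str) -> ToxinConfig:
    return ToxinConfig(
        variant=variant,
        b=params.get("b", 0.0),
        k_toxin=params.get("k_toxin", 0.0),
        toxin_threshold=params.get("toxin_threshold", 0.0),
    )


def screen(
    population: Sequence[ParameterSet],
    units: list[TranscriptionUnitSpec],
    conditions: Sequence[Condition],
    goals: Mapping[str, float] | None = None,
    toxin_variant: str = "TL_TL",
    resources: ResourceSpec | None = None,
    t_end: float = 3 * 3600.0,
    rtol: float = 1e-6,
    atol: float = 1e-12,
    checkpoint_path=None,
    checkpoint_every: int = 50,
) -> ScreenResult:
    """Simulate the grid and score the surrogate criteria for every set.

    Sets whose simulation fails are kept in the population (scored as
    satisfying 0 criteria, terms NaN).  When goals for the median-referenced
    criteria (large_positive, deviation, residual_mrna) are not supplied they
    are set to the population median of the corresponding term, eliminating
    the worse half of the population on each — mirroring how goal thresholds
    without a hard phenotype constraint are chosen.

    Ranking: descending n_satisfied, ties broken by ascending sum of
    population-scaled terms.
    """
    population = list(population)
    reports: list[SurrogateReport | None] = []
    term_rows: list[dict[str, float]] = []
    errors: list[str] = []
    for i, pset in enumerate(population):
        try:
            grid = run_grid(
                units, pset, conditions,
                resources=resources, toxin=_toxin_from(pset, toxin_variant),
                t_end=t_end, rtol=rtol, atol=atol, raise_on_failure=True,
            )
            rep = compute_report(grid, conditions, goals=goals or DEFAULT_GOALS)
            reports.append(rep)
            term_rows.append(rep.terms)
            errors.append("")
        except (SimulationError, ValueError, FloatingPointError, KeyError) as exc:
            reports.append(None)
            term_rows.append({})
            errors.append(str(exc))
        if checkpoint_path is not None and (i + 1) % checkpoint_every == 0:
            pd.DataFrame(term_rows).to_csv(checkpoint_path, index=False)

    terms_df = pd.DataFrame(term_rows)
    final_goals = dict(goals) if goals is not None else dict(DEFAULT_GOALS)
    for name in ("large_positive", "deviation", "residual_mrna"):
        if name not in final_goals and name in terms_df.columns and terms_df[name].notna().any():
            final_goals[name] = float(terms_df[name].median(skipna=True))

    crit_rows, n_sat = [], []
    from .surrogates import evaluate_criteria

    for rep in reports:
        if rep is None:
            crit_rows.append({})
            n_sat.append(0)
            continue
        usable = {k: v for k, v in final_goals.items() if k in rep.terms}
        crit, n = evaluate_criteria(rep.terms, usable)
        rep.criteria, rep.n_satisfied = crit, n
        crit_rows.append(crit)
        n_sat.append(n)

    param_df = pd.DataFrame([p.as_dict() for p in population])
    crit_df = pd.DataFrame(crit_rows).add_prefix("crit_")
    table = pd.concat([param_df, terms_df, crit_df], axis=1)
    table["n_satisfied"] = n_sat
    table["error"] = errors
    # tie-break: sum of population-scaled registry terms (lower = better)
    registry_cols = [c for c in ALL_CRITERIA if c in terms_df.columns]
    if len(table) >= 2 and registry_cols:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scaled = scale_terms(terms_df[registry_cols].to_numpy())
        score = np.nansum(scaled, axis=1)
    else:
        score = np.zeros(len(table))
    table["scaled_term_sum"] = score
    order = np.lexsort((score, -table["n_satisfied"].to_numpy()))
    rank = np.empty(len(table), dtype=int)
    rank[order] = np.arange(1, len(table) + 1)
    table["rank"] = rank
    return ScreenResult(table=table, reports=reports, goals=final_goals)


@dataclass
class OptimizeResult:
    """Best parameter set from multi-start surrogate optimization."""

    params: ParameterSet | None
    objective: float
    feasible: bool
    mode: str
    starts: list[dict] = field(default_factory=list)

    @property
    def any_success(self) -> bool:
        return any(s["success"] for s in self.starts)


def optimize_surrogate(
    term_fn,
    goals: Mapping[str, float],
    mode: str,
    bounds: ParameterBounds | None = None,
    init_population: Sequence[ParameterSet] | None = None,
    n_starts: int = 8,
    seed: int = 0,
    feasibility_range: tuple[float, float] = (1e-8, 1e8),
    maxiter: int = 100,
) -> OptimizeResult:
    """Surrogate-objective optimization in log-parameter space.

    ``term_fn(params: ParameterSet) -> dict[str, float]`` evaluates the
    surrogate terms (typically by simulating a grid).  Two modes:

    soft
        the terms are scaled onto [-15, 15] using the init population's
        per-term range and their sum minimized from each start with a
        bound-constrained quasi-Newton method (bounds required).
    feasibility
        the goals are hard constraints; each start minimizes the summed
        squared constraint violation sum(max(0, term - goal)^2), with starts
        drawn log-uniformly on ``feasibility_range`` and no bounds enforced.
        A start reaching zero violation is feasible.

    Returns the best start; if no start's solver reports success, the result
    carries ``params=None`` and ``any_success=False`` rather than a silent
    best.
    """
    from scipy.optimize import minimize

    rng = np.random.default_rng(seed)
    mode = str(mode)
    if mode not in ("soft", "feasibility"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "soft" and bounds is None:
        raise ValueError("soft mode requires parameter bounds")

    if mode == "soft":
        names, lo, hi = bounds.log_arrays()
        if init_population is None:
            init_population = lhs_sample(bounds, max(n_starts, 2), seed)
        pop_terms = pd.DataFrame([term_fn(p) for p in init_population])
        goal_names = [g for g in goals if g in pop_terms.columns]
        t_lo = pop_terms[goal_names].min(axis=0).to_numpy()
        t_hi = pop_terms[goal_names].max(axis=0).to_numpy()
        span = np.where(t_hi > t_lo, t_hi - t_lo, 1.0)

        def objective(x):
            p = ParameterSet({n: 10.0 ** v for n, v in zip(names, x)})
            terms = term_fn(p)
            vals = np.array([terms[g] for g in goal_names])
            scaled = (vals - t_lo) / span * 30.0 - 15.0
            return float(np.sum(scaled))

        starts = [
            np.log10([init_population[i % len(init_population)][n] for n in names])
            for i in range(n_starts)
        ]
        opt_bounds = list(zip(lo, hi))
    else:
        names = sorted(goals_param_names(term_fn, goals))
        lo_v, hi_v = np.log10(feasibility_range[0]), np.log10(feasibility_range[1])

        def objective(x):
            p = ParameterSet({n: 10.0 ** v for n, v in zip(names, x)})
            terms = term_fn(p)
            viol = [max(0.0, terms[g] - goals[g]) for g in goals if g in terms]
            return float(np.sum(np.square(viol)))

        starts = [rng.uniform(lo_v, hi_v, size=len(names)) for _ in range(n_starts)]
        opt_bounds = None

    records = []
    best = None
    for x0 in starts:
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=opt_bounds,
            options={"maxiter": maxiter},
        )
        rec = {
            "success": bool(res.success),
            "objective": float(res.fun),
            "status": int(res.status),
            "message": str(res.message),
            "x": res.x.copy(),
        }
        if mode == "feasibility":
            rec["feasible"] = res.fun <= 1e-12
        records.append(rec)
        if rec["success"] and (best is None or res.fun < best["objective"]):
            best = rec

    if best is None:
        return OptimizeResult(params=None, objective=float("nan"), feasible=False,
                              mode=mode, starts=records)
    params = ParameterSet({n: 10.0 ** v for n, v in zip(names, best["x"])})
    feasible = bool(best.get("feasible", False)) if mode == "feasibility" else True
    return OptimizeResult(params=params, objective=best["objective"],
                          feasible=feasible, mode=mode, starts=records)


def goals_param_names(term_fn, goals) -> list[str]:
    """Parameter names the feasibility search optimizes over.

    The term function advertises its free parameters via a ``param_names``
    attribute; this keeps toy objectives (for which the search space is a
    handful of constants) and full grid objectives uniform.
    """
    names = getattr(term_fn, "param_names", None)
    if names is None:
        raise ValueError("term_fn must expose .param_names for feasibility mode")
    return list(names)
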