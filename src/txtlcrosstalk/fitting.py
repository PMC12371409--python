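"""Least-squares estimation of kinetic parameters from time-course tables.

Observed data enter as a tidy table (condition_id, replicate, time_s, value)
— the melted form of a plate-reader export after calibration to nM.
Replicates are averaged and the residual between the averaged trace and the
simulated readout is minimized over log10-transformed free parameters with a
damped (trust-region) nonlinear least-squares solver, optionally from
multiple log-uniform starts within the bounds.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .experiments import Condition, compose_doses
from .network import build_network
from .parameters import ParameterBounds, ParameterSet
from .simulate import simulate
from .units import ResourceSpec, ToxinConfig, TranscriptionUnitSpec

__all__ = ["FitResult", "fit_timecourses", "TimecourseObjective"]


class TimecourseObjective:
    """Residuals of replicate-averaged observed traces vs simulated readouts."""

    def __init__(
        self,
        data: pd.DataFrame,
        units: list[TranscriptionUnitSpec],
        base_params: ParameterSet,
        free_names: Sequence[str],
        toxin_variant: str = "TL_TL",
        resources: ResourceSpec | None = None,
        rtol: float = 1e-6,
        atol: float = 1e-12,
        empty_conc: float = 10.0,
    ):
        required = {"condition_id", "replicate", "time_s", "value"}
        if not required.issubset(data.columns):
            raise ValueError(f"data must have columns {sorted(required)}")
        if data["value"].isna().all():
            raise ValueError("all observations are NaN")
        self.units = units
        self.base_params = base_params
        self.free_names = list(free_names)
        self.toxin_variant = toxin_variant
        self.resources = resources
        self.rtol, self.atol = rtol, atol
        avg = (
            data.dropna(subset=["value"])
            .groupby(["condition_id", "time_s"], as_index=False)["value"]
            .mean()
        )
        self.observations: list[tuple[Condition, np.ndarray, np.ndarray]] = []
        for cid, sub in avg.groupby("condition_id"):
            cond = Condition.from_id(str(cid), empty_conc=empty_conc)
            times = sub["time_s"].to_numpy(dtype=float)
            order = np.argsort(times)
            self.observations.append(
                (cond, times[order], sub["value"].to_numpy(dtype=float)[order])
            )
        if not self.observations:
            raise ValueError("no usable observations")
        self.n_obs = sum(len(t) for _, t, _ in self.observations)
        self._net_cache: dict = {}

    def params_from_log(self, x: np.ndarray) -> ParameterSet:
        return self.base_params.updated(
            {n: 10.0 ** v for n, v in zip(self.free_names, x)}
        )

    def __call__(self, x: np.ndarray) -> np.ndarray:
        params = self.params_from_log(x)
        res = []
        for cond, times, values in self.observations:
            doses = compose_doses(cond)
            key = frozenset(doses.dna_doses)
            net = self._net_cache.get(key)
            if net is None:
                net = build_network(
                    [u for u in self.units if u.id in doses.dna_doses],
                    self.resources,
                    ToxinConfig(
                        self.toxin_variant,
                        b=params.get("b", 0.0),
                        k_toxin=params.get("k_toxin", 0.0),
                        toxin_threshold=params.get("toxin_threshold", 0.0),
                    ),
                )
                self._net_cache[key] = net
            t_end = float(times[-1])
            tc = simulate(
                net, params, doses, t_end=t_end, t_step=max(t_end / 200.0, 1.0),
                rtol=self.rtol, atol=self.atol, condition_id=cond.condition_id,
            )
            sim = np.interp(times, tc.times, tc.readouts[cond.reporter_unit])
            res.append(sim - values)
        return np.concatenate(res)


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics of a time-course fit.

    Standard errors come from the Gauss-Newton covariance
    sigma^2 (J^T J)^-1 at the optimum (sigma^2 = 2 cost / dof), propagated to
    the natural scale of each parameter; they are asymptotic and conditional
    on the model structure.
    """

    params: ParameterSet
    free_names: list[str]
    estimates: np.ndarray  # natural scale
    log_estimates: np.ndarray
    bse_log: np.ndarray  # standard errors of log10 estimates
    cost: float
    residual_norm: float
    n_obs: int
    success: bool
    message: str
    n_starts: int = 1
    start_costs: list[float] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Time-course least-squares fit",
            "=" * 64,
            f"observations: {self.n_obs}    free parameters: {len(self.free_names)}",
            f"cost: {self.cost:.6g}    residual RMS: {self.residual_norm:.6g}",
            f"starts: {self.n_starts}    converged: {self.success}",
            "-" * 64,
            f"{'parameter':<24}{'estimate':>14}{'log10':>10}{'se(log10)':>12}",
            "-" * 64,
        ]
        for name, est, lg, se in zip(
            self.free_names, self.estimates, self.log_estimates, self.bse_log
        ):
            lines.append(f"{name:<24}{est:>14.5g}{lg:>10.3f}{se:>12.3g}")
        lines.append("=" * 64)
        return "\n".join(lines)


def fit_timecourses(
    data: pd.DataFrame,
    units: list[TranscriptionUnitSpec],
    init: ParameterSet,
    free_names: Sequence[str],
    bounds: ParameterBounds | None = None,
    n_starts: int = 1,
    seed: int = 0,
    toxin_variant: str = "TL_TL",
    resources: ResourceSpec | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    **ls_kwargs,
) -> FitResult:
    """Fit ``free_names`` to replicate-averaged time courses.

    Damped least squares in log10-parameter space: Levenberg-Marquardt when
    unbounded, trust-region-reflective when bounds are given.  Multi-start
    (``n_starts`` > 1) draws additional log-uniform starts within the bounds
    and returns the best.

    The finite-difference Jacobian step (``diff_step``, default 1e-3 decades)
    is kept well above the integrator's relative tolerance so numerical noise
    in the trajectories cannot corrupt the descent direction.
    """
    ls_kwargs.setdefault("diff_step", 1e-3)
    free_names = list(free_names)
    if bounds is not None:
        for n in free_names:
            if n in bounds.lower and not (bounds.lower[n] <= init[n] <= bounds.upper[n]):
                raise ValueError(f"initial value of {n!r} outside bounds")
    obj = TimecourseObjective(
        data, units, init, free_names, toxin_variant=toxin_variant,
        resources=resources, rtol=rtol, atol=atol,
    )
    x0 = np.log10([init[n] for n in free_names])
    if bounds is not None:
        lb = np.array([np.log10(bounds.lower.get(n, 1e-300)) for n in free_names])
        ub = np.array([np.log10(bounds.upper.get(n, 1e300)) for n in free_names])
        method = "trf"
        ls_bounds = (lb, ub)
    else:
        method = "lm"
        ls_bounds = (-np.inf, np.inf)

    rng = np.random.default_rng(seed)
    starts = [x0]
    if n_starts > 1:
        if bounds is None:
            raise ValueError("multi-start requires bounds to sample starts from")
        for _ in range(n_starts - 1):
            starts.append(rng.uniform(lb, ub))

    best = None
    start_costs = []
    for x_init in starts:
        sol = least_squares(obj, x_init, method=method, bounds=ls_bounds, **ls_kwargs)
        start_costs.append(float(sol.cost))
        if best is None or sol.cost < best.cost:
            best = sol

    dof = max(obj.n_obs - len(free_names), 1)
    sigma2 = 2.0 * best.cost / dof
    JTJ = best.jac.T @ best.jac
    try:
        cov = sigma2 * np.linalg.inv(JTJ)
        bse_log = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        bse_log = np.full(len(free_names), np.nan)

    fitted = obj.params_from_log(best.x)
    return FitResult(
        params=fitted,
        free_names=free_names,
        estimates=10.0 ** best.x,
        log_estimates=best.x,
        bse_log=bse_log,
        cost=float(best.cost),
        residual_norm=float(np.sqrt(2 * best.cost / obj.n_obs)),
        n_obs=obj.n_obs,
        success=bool(best.success),
        message=str(best.message),
        n_starts=len(starts),
        start_costs=start_costs,
    )
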