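"""High-level modelling interface: a model object built from data/config,
whose ``fit`` returns a results object with estimates and a summary table.

    >>> model = CrosstalkModel.default()
    >>> tc = model.simulate(Condition("sfGFP", "sig70_strong", 2.5, "reporter_only"))
    >>> grid = model.run_grid(enumerate_conditions("sfGFP"))
    >>> report = model.surrogate_report(grid, enumerate_conditions("sfGFP"))
    >>> results = model.fit(observed_table, free_names=["k_deg_sfGFP", "RNase0"],
    ...                     bounds=default_bounds())
    >>> print(results.summary())
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import pandas as pd

from .experiments import Condition, GridResult, compose_doses, run_grid
from .fitting import FitResult, fit_timecourses
from .network import ReactionNetwork, build_network
from .parameters import ParameterBounds, ParameterSet, reference_parameters
from .simulate import DoseSchedule, TimeCourse, simulate
from .surrogates import DEFAULT_GOALS, SurrogateReport, compute_report
from .units import ResourceSpec, ToxinConfig, TranscriptionUnitSpec, default_registry

__all__ = ["CrosstalkModel"]


class CrosstalkModel:
    """A TXTL crosstalk model: construct registry + parameters + toxin variant.

    The model owns the structural declaration (transcription units, resource
    pools, toxin mechanism) and a parameter set; simulation, grid evaluation,
    surrogate reporting and fitting are methods.  ``fit`` returns a
    :class:`~txtlcrosstalk.fitting.FitResult` carrying estimates, asymptotic
    standard errors and a ``summary()`` table.
    """

    def __init__(
        self,
        units: list[TranscriptionUnitSpec],
        params: ParameterSet | Mapping[str, float] | None = None,
        toxin_variant: str = "TL_TL",
        resources: ResourceSpec | None = None,
    ):
        self.units = list(units)
        self.params = (
            params if isinstance(params, ParameterSet)
            else ParameterSet(params) if params is not None
            else reference_parameters()
        )
        self.toxin_variant = toxin_variant
        self.resources = resources or ResourceSpec()

    # -- constructors ---------------------------------------------------------

    @classmethod
    def default(cls, toxin_variant: str = "TL_TL") -> "CrosstalkModel":
        """The 10-unit registry with the reference parameterization."""
        return cls(default_registry(), reference_parameters(), toxin_variant)

    @classmethod
    def from_config(cls, path) -> "CrosstalkModel":
        from .config import load_config

        cfg = load_config(path)
        return cls(
            cfg.units, cfg.parameters, toxin_variant=cfg.toxin.variant,
            resources=cfg.resources,
        )

    # -- structure ------------------------------------------------------------

    @property
    def toxin_config(self) -> ToxinConfig:
        p = self.params
        return ToxinConfig(
            self.toxin_variant,
            b=p.get("b", 0.0),
            k_toxin=p.get("k_toxin", 0.0),
            toxin_threshold=p.get("toxin_threshold", 0.0),
        )

    def network(self, unit_ids: Iterable[str] | None = None) -> ReactionNetwork:
        units = (
            self.units
            if unit_ids is None
            else [u for u in self.units if u.id in set(unit_ids)]
        )
        return build_network(units, self.resources, self.toxin_config)

    def with_params(self, **updates: float) -> "CrosstalkModel":
        return CrosstalkModel(
            self.units, self.params.replace(**updates), self.toxin_variant, self.resources
        )

    # -- simulation -----------------------------------------------------------

    def simulate(
        self,
        condition_or_doses: Condition | DoseSchedule,
        t_end: float = 3 * 3600.0,
        t_step: float = 300.0,
        prune: bool = True,
        **kwargs,
    ) -> TimeCourse:
        if isinstance(condition_or_doses, Condition):
            doses = compose_doses(condition_or_doses)
            cid = condition_or_doses.condition_id
        else:
            doses = condition_or_doses
            cid = kwargs.pop("condition_id", "")
        dosed = set(doses.dna_doses) | set(doses.rna_doses)
        net = self.network(dosed if prune else None)
        return simulate(
            net, self.params, doses, t_end=t_end, t_step=t_step,
            condition_id=cid, **kwargs,
        )

    def run_grid(self, conditions: Sequence[Condition], **kwargs) -> GridResult:
        return run_grid(
            self.units, self.params, conditions,
            resources=self.resources, toxin=self.toxin_config, **kwargs,
        )

    def surrogate_report(
        self,
        grid: GridResult,
        conditions: Sequence[Condition],
        goals: Mapping[str, float] | None = None,
        reference_ratios: pd.DataFrame | None = None,
    ) -> SurrogateReport:
        return compute_report(
            grid, conditions, goals=goals or DEFAULT_GOALS,
            reference_ratios=reference_ratios,
        )

    # -- estimation -----------------------------------------------------------

    def fit(
        self,
        data: pd.DataFrame,
        free_names: Sequence[str],
        bounds: ParameterBounds | None = None,
        n_starts: int = 1,
        seed: int = 0,
        **kwargs,
    ) -> FitResult:
        """Least-squares fit of ``free_names`` to a tidy time-course table."""
        return fit_timecourses(
            data, self.units, self.params, free_names, bounds=bounds,
            n_starts=n_starts, seed=seed, toxin_variant=self.toxin_variant,
            resources=self.resources, **kwargs,
        )
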