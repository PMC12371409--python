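"""LHS stratification, heuristic filter, screening, fitting, optimization."""

import numpy as np
import pandas as pd
import pytest

from txtlcrosstalk import (
    ParameterBounds,
    ParameterSet,
    enumerate_conditions,
    filter_population,
    fit_timecourses,
    heuristic_filter,
    lhs_sample,
    optimize_surrogate,
    screen,
)
from txtlcrosstalk.parameters import default_bounds, reference_parameters


def _tiny_bounds(names, lo=1e-3, hi=1e3):
    return ParameterBounds(lower={n: lo for n in names}, upper={n: hi for n in names})


class TestLhsSample:
    def test_single_point_inside_bounds(self):
        b = _tiny_bounds(["a", "b"])
        (p,) = lhs_sample(b, 1, seed=0)
        assert 1e-3 <= p["a"] <= 1e3 and 1e-3 <= p["b"] <= 1e3

    def test_log_space_stratification_one_sample_per_bin(self):
        """n=100 samples -> exactly one in each of 100 equal log-width bins."""
        n = 100
        b = _tiny_bounds(["a", "b", "c"], lo=1e-4, hi=1e4)
        pop = lhs_sample(b, n, seed=42)
        edges = np.linspace(-4, 4, n + 1)
        for name in ("a", "b", "c"):
            logs = np.log10([p[name] for p in pop])
            counts, _ = np.histogram(logs, bins=edges)
            assert (counts == 1).all()

    def test_same_seed_identical_populations(self):
        b = default_bounds()
        pop1 = lhs_sample(b, 10, seed=7)
        pop2 = lhs_sample(b, 10, seed=7)
        for p1, p2 in zip(pop1, pop2):
            assert p1.as_dict() == p2.as_dict()

    def test_fixed_parameters_pinned(self):
        b = ParameterBounds(lower={"a": 1e-2}, upper={"a": 1e2}, fixed={"z": 5.0})
        pop = lhs_sample(b, 3, seed=0)
        assert all(p["z"] == 5.0 for p in pop)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            lhs_sample(_tiny_bounds(["a"]), 0, seed=0)


class TestHeuristicFilter:
    def test_reference_parameters_pass(self, ref_params):
        assert heuristic_filter(ref_params)

    def test_t7_affinity_ordering_violation_rejected(self, ref_params):
        # Kd(T7 strong) > Kd(T7 weak) violates rule (i)
        bad = ref_params.replace(kr_tx_T7_strong=1e3)
        assert not heuristic_filter(bad)

    def test_sig70_weak_must_be_weakest(self, ref_params):
        bad = ref_params.replace(kr_tx_sig70_weak=1e-4)
        assert not heuristic_filter(bad)

    def test_reporter_nuclease_affinity_must_be_weaker(self, ref_params):
        bad = ref_params.replace(kr_nuc_sfGFP=1e-6)
        assert not heuristic_filter(bad)

    def test_empty_vector_must_degrade_fastest(self, ref_params):
        bad = ref_params.replace(k_deg_empty=1e-4)
        assert not heuristic_filter(bad)

    def test_missing_parameter_raises(self):
        with pytest.raises(KeyError):
            heuristic_filter({"kf_tx_T7_strong": 1.0})

    def test_invariant_under_kd_preserving_rescaling(self, ref_params):
        """Scaling every (kf, kr) pair by the same factor preserves all Kds
        and therefore the filter outcome."""
        scaled = {}
        for k, v in ref_params.items():
            if k.startswith(("kf_", "kr_")):
                scaled[k] = v * 37.0
            else:
                scaled[k] = v
        assert heuristic_filter(ref_params) == heuristic_filter(scaled) == True

    def test_rule_one_alone_accepts_half_by_symmetry(self, ref_params):
        """With i.i.d. log-uniform T7 Kds and rules (ii)-(iv) forced true,
        acceptance frequency is ~1/2 (Monte Carlo against the symmetry
        argument: P(Kd_strong < Kd_weak) = 1/2 for exchangeable draws)."""
        rng = np.random.default_rng(123)
        n, hits = 4000, 0
        base = ref_params.as_dict()
        for _ in range(n):
            kd_s, kd_w = 10.0 ** rng.uniform(-2, 2, size=2)
            p = dict(base)
            p["kf_tx_T7_strong"], p["kr_tx_T7_strong"] = 1.0, kd_s
            p["kf_tx_T7_weak"], p["kr_tx_T7_weak"] = 1.0, kd_w
            p["kr_tx_sig70_weak"] = 1e9  # keep rule (ii) satisfied for any draw
            hits += heuristic_filter(p)
        assert abs(hits / n - 0.5) < 0.03


class TestScreen:
    def test_empty_population(self, registry):
        res = screen([], registry, enumerate_conditions("sfGFP")[:4])
        assert len(res) == 0

    def test_reference_set_ranks_first_in_mixed_population(self, ref_params, registry):
        """The shipped parameterization outranks detuned variants on the
        key-trend criteria."""
        detuned1 = ref_params.replace(k_toxin=0.0)  # no toxin -> no baseline decrease
        detuned2 = ref_params.replace(RNase0=1e4)  # nuclease excess -> no distraction
        conds = enumerate_conditions("sfGFP")
        res = screen([detuned1, ref_params, detuned2], registry, conds)
        table = res.table.sort_values("rank")
        assert table.iloc[0]["k_toxin"] == ref_params["k_toxin"]
        assert table.iloc[0]["n_satisfied"] >= 6

    def test_toxin_disabled_population_fails_strong_baseline(self, ref_params, registry):
        """k_toxin = 0 everywhere: resource depletion alone cannot produce the
        high-dose decrease, so the strong-promoter baseline criterion fails."""
        pop = [ref_params.replace(k_toxin=0.0), ref_params.replace(k_toxin=0.0, b=0.0)]
        res = screen(pop, registry, enumerate_conditions("sfGFP"))
        assert not res.table["crit_baseline_strong"].any()

    def test_failed_simulation_scored_zero(self, ref_params, registry):
        broken = ref_params.replace(kf_tx_T7_strong=1e15)  # absurd stiffness
        conds = enumerate_conditions("sfGFP", promoters=["T7_strong"], concs=[3e4])
        res = screen([broken], registry, conds)
        row = res.table.iloc[0]
        assert row["n_satisfied"] == 0


class TestFit:
    def _fixture_data(self, ref_model, conds, cv=0.0, seed=0):
        from txtlcrosstalk import FixtureSpec, generate_fixture

        spec = FixtureSpec(ref_model.params, cv=cv, replicates=3, seed=seed,
                           t_end=3600.0, t_step=600.0)
        table, meta = generate_fixture(spec, conds, ref_model.units)
        return table, meta

    def test_noise_free_fit_is_fixed_point(self, ref_model):
        conds = enumerate_conditions("sfGFP", promoters=["sig70_strong"],
                                     concs=[2.5], combos=["reporter_only"])
        data, _ = self._fixture_data(ref_model, conds, cv=0.0)
        res = fit_timecourses(
            data, ref_model.units, ref_model.params, ["k_deg_sfGFP"],
        )
        assert res.cost < 1e-4
        assert res.params["k_deg_sfGFP"] == pytest.approx(
            ref_model.params["k_deg_sfGFP"], rel=1e-3
        )
        assert "k_deg_sfGFP" in res.summary()

    def test_init_outside_bounds_rejected(self, ref_model):
        conds = enumerate_conditions("sfGFP", promoters=["sig70_strong"],
                                     concs=[2.5], combos=["reporter_only"])
        data, _ = self._fixture_data(ref_model, conds)
        bounds = ParameterBounds(lower={"k_deg_sfGFP": 1.0}, upper={"k_deg_sfGFP": 10.0})
        with pytest.raises(ValueError, match="outside bounds"):
            fit_timecourses(data, ref_model.units, ref_model.params,
                            ["k_deg_sfGFP"], bounds=bounds)

    def test_all_nan_data_rejected(self, ref_model):
        df = pd.DataFrame(
            {"condition_id": ["sfGFP|T7_strong|1|reporter_only"], "replicate": [1],
             "time_s": [0.0], "value": [np.nan]}
        )
        with pytest.raises(ValueError, match="NaN"):
            fit_timecourses(df, ref_model.units, ref_model.params, ["k_deg_sfGFP"])


class TestOptimizeSurrogate:
    """Toy objectives: terms are simple functions of two parameters, so the
    feasible box is known analytically."""

    @staticmethod
    def _toy_terms(p):
        # feasible iff a <= 1 and b <= 1 (log10 a <= 0, log10 b <= 0)
        return {"t1": np.log10(p["a"]), "t2": np.log10(p["b"])}

    _toy_terms.__func__.param_names = ["a", "b"]

    def test_feasibility_mode_lands_in_known_box(self):
        term_fn = self._toy_terms
        goals = {"t1": 0.0, "t2": 0.0}
        res = optimize_surrogate(term_fn, goals, mode="feasibility",
                                 n_starts=6, seed=3)
        assert res.any_success and res.feasible
        assert res.params["a"] <= 1.0 + 1e-6 and res.params["b"] <= 1.0 + 1e-6

    def test_feasible_start_is_immediately_feasible(self):
        term_fn = self._toy_terms
        goals = {"t1": 0.0, "t2": 0.0}
        res = optimize_surrogate(term_fn, goals, mode="feasibility",
                                 n_starts=1, seed=12,
                                 feasibility_range=(1e-4, 1e-1))
        assert res.feasible and res.objective == 0.0

    def test_soft_mode_decreases_objective(self):
        bounds = ParameterBounds(lower={"a": 1e-3, "b": 1e-3},
                                 upper={"a": 1e3, "b": 1e3})
        init = [ParameterSet({"a": 100.0, "b": 100.0}),
                ParameterSet({"a": 0.01, "b": 0.01})]
        res = optimize_surrogate(self._toy_terms, {"t1": 0.0, "t2": 0.0},
                                 mode="soft", bounds=bounds,
                                 init_population=init, n_starts=2)
        assert res.any_success
        # optimum pushes both parameters to the lower bound of the box
        assert res.params["a"] == pytest.approx(1e-3, rel=1e-2)

    def test_soft_mode_requires_bounds(self):
        with pytest.raises(ValueError, match="bounds"):
            optimize_surrogate(self._toy_terms, {"t1": 0.0}, mode="soft")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            optimize_surrogate(self._toy_terms, {}, mode="banana")
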