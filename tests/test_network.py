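"""Network construction, rate evaluation, gate analytics, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from txtlcrosstalk import (
    Condition,
    DoseSchedule,
    ResourceSpec,
    ToxinConfig,
    build_network,
    compose_doses,
    conservation_totals,
    default_registry,
    evaluate_rhs,
    simulate,
    toxin_gate,
)
from txtlcrosstalk.network import GLOBAL_SPECIES, NetworkError

from conftest import naive_rhs


class TestBuildNetwork:
    def test_default_registry_has_ten_units(self, registry):
        # sfGFP x4 promoters + aptamer x3 + empty x2 + kanR
        assert len(registry) == 10
        net = build_network(registry)
        assert len(net.units) == 10

    def test_empty_unit_list_gives_globals_and_lone_drain(self):
        net = build_network([], toxin=ToxinConfig("off", b=2.0))
        assert net.species == list(GLOBAL_SPECIES)
        assert len(net.reactions) == 1
        assert net.reactions[0].name == "toxin_drain"

    def test_single_untranslated_unit_species_count(self, one_unit_untranslated):
        # DNA, DNA:pol, mRNA, mRNA:nuclease + 7 globals
        net = build_network([one_unit_untranslated])
        assert net.n_species == 11
        for sp in ("DNA_apt", "C_tx_apt", "mRNA_apt", "C_deg_apt"):
            assert sp in net.species
        assert "C_tl_apt" not in net.species

    def test_translatable_unit_gains_complex_protein_and_mature(self, one_unit_translatable):
        net = build_network([one_unit_translatable])
        for sp in ("C_tl_rep", "P_rep", "F_rep"):
            assert sp in net.species

    def test_duplicate_unit_ids_rejected(self, one_unit_untranslated):
        with pytest.raises(NetworkError, match="duplicate"):
            build_network([one_unit_untranslated, one_unit_untranslated])

    def test_untranslated_with_protein_length_rejected(self, one_unit_untranslated):
        from dataclasses import replace

        with pytest.raises(ValueError, match="protein_length"):
            replace(one_unit_untranslated, protein_length=10)

    def test_unknown_toxin_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            ToxinConfig("TX_OFF")

    def test_stoichiometry_shape_matches_reactions(self, registry):
        net = build_network(registry)
        assert net.stoichiometry.shape == (net.n_species, len(net.reactions))
        assert len(net.rate_laws) == len(net.reactions)


class TestEvaluateRhs:
    def test_all_zero_state_only_toxin_drains(self, registry):
        tox = ToxinConfig("TL_TL", b=3.5, k_toxin=0.1, toxin_threshold=100.0)
        net = build_network(registry, toxin=tox)
        dydt = evaluate_rhs(net, np.zeros(net.n_species), {"b": 3.5})
        expected = np.zeros(net.n_species)
        expected[net.species_index["toxin"]] = -3.5
        np.testing.assert_allclose(dydt, expected, atol=1e-14)

    def test_gate_factor_is_one_at_threshold(self, one_unit_translatable):
        tox = ToxinConfig("TL_TL", b=0.0, k_toxin=0.05, toxin_threshold=50.0)
        net = build_network([one_unit_translatable], toxin=tox)
        state = np.zeros(net.n_species)
        state[net.species_index["Ribo"]] = 200.0
        state[net.species_index["toxin"]] = 50.0  # exactly at threshold
        dydt = evaluate_rhs(net, state, {"k_toxin": 0.05, "toxin_threshold": 50.0, "b": 0.0})
        # rate = k_toxin * (1 + tanh(0)) * [Ribo] = 0.05 * 200
        assert dydt[net.species_index["Ribo"]] == pytest.approx(-0.05 * 200.0)

    def test_dimension_mismatch_and_nonfinite_rejected(self, one_unit_untranslated):
        net = build_network([one_unit_untranslated])
        with pytest.raises(NetworkError, match="shape"):
            evaluate_rhs(net, np.zeros(3), {})
        bad = np.zeros(net.n_species)
        bad[0] = np.nan
        with pytest.raises(NetworkError, match="finite"):
            evaluate_rhs(net, bad, {})

    @pytest.mark.parametrize("variant", ["TL_TL", "TX_TX", "TL_TX", "TX_TL", "off"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_stoichiometry_oracle(
        self, one_unit_translatable, one_unit_untranslated, variant, seed
    ):
        """Compiled vectorised RHS == naive per-reaction oracle on random states."""
        rng = np.random.default_rng(seed)
        tox = ToxinConfig(variant, b=0.7, k_toxin=0.03, toxin_threshold=5.0)
        net = build_network([one_unit_translatable, one_unit_untranslated], toxin=tox)
        params = {"k_tx_elong": 40.0, "k_tl_elong": 4.0, "b": 0.7, "k_toxin": 0.03,
                  "toxin_threshold": 5.0}
        for _ in range(5):
            state = rng.uniform(0, 50, size=net.n_species)
            state[net.species_index["toxin"]] = rng.uniform(-10, 20)
            np.testing.assert_allclose(
                evaluate_rhs(net, state, params),
                naive_rhs(net, state, params),
                rtol=1e-12, atol=1e-12,
            )

    def test_toxin_source_follows_variant(self, one_unit_translatable):
        """TL-source toxin grows with translation flux, TX-source with transcription."""
        state_template = None
        rates = {}
        for variant in ("TL_TL", "TX_TX"):
            tox = ToxinConfig(variant, b=0.0, k_toxin=0.0, toxin_threshold=1e9)
            net = build_network([one_unit_translatable], toxin=tox)
            state = np.zeros(net.n_species)
            state[net.species_index["C_tl_rep"]] = 10.0
            state[net.species_index["C_tx_rep"]] = 10.0
            state[net.species_index["AA"]] = 1e9
            state[net.species_index["NTP"]] = 1e9
            dydt = evaluate_rhs(
                net, state,
                {"k_tl_elong": 4.0, "k_tx_elong": 40.0, "b": 0.0, "K_AA": 0.0, "K_NTP": 0.0},
            )
            rates[variant] = dydt[net.species_index["toxin"]]
        assert rates["TL_TL"] == pytest.approx(4.0 / 250 * 10.0, rel=1e-9)
        assert rates["TX_TX"] == pytest.approx(40.0 / 900 * 10.0, rel=1e-9)


class TestToxinGate:
    def test_unity_at_threshold_and_limits(self):
        cfg = ToxinConfig("TL_TL", toxin_threshold=42.0)
        assert toxin_gate(42.0, cfg) == pytest.approx(1.0)
        assert toxin_gate(-1e6, cfg) == pytest.approx(0.0, abs=1e-12)
        assert toxin_gate(1e6, cfg) == pytest.approx(2.0)

    @given(
        a=st.floats(-50, 50, allow_nan=False),
        b=st.floats(-50, 50, allow_nan=False),
        thr=st.floats(-10, 10, allow_nan=False),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_and_bounded(self, a, b, thr):
        cfg = ToxinConfig("TL_TL", toxin_threshold=thr)
        ga, gb = toxin_gate(a, cfg), toxin_gate(b, cfg)
        assert 0.0 <= ga <= 2.0 and 0.0 <= gb <= 2.0
        if a < b:
            assert ga <= gb


class TestConservation:
    def test_freshly_dosed_state_totals_equal_initials(self, registry, ref_params):
        net = build_network(registry)
        cond = Condition("sfGFP", "T7_strong", 10.0, "empty_sig70_strong")
        y0 = net.initial_state(ref_params, compose_doses(cond).dna_doses)
        totals = conservation_totals(net, y0)
        assert totals["RNAP_native"] == pytest.approx(ref_params["RNAP0_native"])
        assert totals["RNAP_T7"] == pytest.approx(ref_params["RNAP0_T7"])
        assert totals["Ribo"] == pytest.approx(ref_params["Ribo0"])
        assert totals["RNase"] == pytest.approx(ref_params["RNase0"])

    def test_mid_simulation_totals_conserved_without_toxin(self, registry, ref_params):
        p = ref_params.replace(k_toxin=0.0)
        net = build_network(
            registry, toxin=ToxinConfig("TL_TL", b=1.0, k_toxin=0.0, toxin_threshold=0.0)
        )
        cond = Condition("sfGFP", "sig70_strong", 10.0, "empty_T7_strong")
        tc = simulate(net, p, compose_doses(cond), t_end=3600.0, t_step=600.0)
        t0_totals = conservation_totals(net, tc.trajectories[:, 0])
        for k in range(1, len(tc.times)):
            totals = conservation_totals(net, tc.trajectories[:, k])
            for res, v0 in t0_totals.items():
                assert totals[res] == pytest.approx(v0, rel=1e-4)

    def test_tl_tl_past_threshold_depletes_ribosomes(self, registry, ref_params):
        net = build_network(
            registry,
            toxin=ToxinConfig(
                "TL_TL", b=ref_params["b"], k_toxin=ref_params["k_toxin"],
                toxin_threshold=ref_params["toxin_threshold"],
            ),
        )
        cond = Condition("sfGFP", "T7_strong", 30.0, "reporter_only")
        tc = simulate(net, ref_params, compose_doses(cond))
        final = conservation_totals(net, tc.trajectories[:, -1])
        assert tc.readouts["toxin"].max() > ref_params["toxin_threshold"]
        assert final["Ribo"] < ref_params["Ribo0"] * 0.9
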