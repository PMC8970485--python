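"""Cross-feeding bi-culture ODE: balances, limits, sweeps, trend labels."""

import numpy as np
import pandas as pd
import pytest

import dropcult.crossfeed_ode as ode
from dropcult.crossfeed_ode import (
    CommunityState,
    MediumCondition,
    StrainParams,
    classify_trend,
    default_strains,
    initial_state,
    medium_for_scenario,
    monoculture_strain,
    rhs,
    simulate,
    sweep_density,
    trajectory_to_frame,
)
from dropcult.droplet_model import density_for_lambda

N0_55 = density_for_lambda(5.0, 55.0)


def symmetric_pair(alpha, beta, **kw):
    """Abstract one-amino-acid-each-way mutualists for symmetry checks."""
    a = StrainParams("A", frozenset({"aa2"}), frozenset({"aa1"}),
                     {"aa1": alpha}, {"aa2": beta}, **kw)
    b = StrainParams("B", frozenset({"aa1"}), frozenset({"aa2"}),
                     {"aa2": alpha}, {"aa1": beta}, **kw)
    return a, b


class TestStrainParams:
    def test_overlapping_required_secreted_rejected(self):
        with pytest.raises(ValueError):
            StrainParams("X", frozenset({"lysine"}), frozenset({"lysine"}),
                         {"lysine": 1e-9}, {"lysine": 1e-9})

    def test_alpha_outside_secreted_rejected(self):
        with pytest.raises(ValueError):
            StrainParams("X", frozenset({"a"}), frozenset({"b"}),
                         {"a": 1e-9}, {"a": 1e-9})

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            StrainParams("X", frozenset({"a"}), frozenset({"b"}),
                         {"b": -1e-9}, {"a": 1e-9})


class TestRhs:
    def test_no_carbon_no_growth(self):
        strains = default_strains()
        state = CommunityState(0.0, {s.name: 1e7 for s in strains}, 0.0,
                               {"isoleucine": 3.0, "valine": 3.0, "leucine": 3.0,
                                "lysine": 3.0})
        d = rhs(state, strains)
        assert all(v == 0.0 for v in d.biomass.values())
        assert d.glucose_g_l == 0.0

    def test_hard_auxotrophy_flat(self):
        # required amino acid absent and nothing produces it -> no growth
        s1 = monoculture_strain()
        state = CommunityState(0.0, {s1.name: 1e7}, 5.0,
                               {aa: 0.0 for aa in s1.required_aa})
        d = rhs(state, [s1])
        assert d.biomass[s1.name] == 0.0

    def test_saturated_monod_limit(self):
        s1 = monoculture_strain()
        state = CommunityState(0.0, {s1.name: 1e7}, 500.0,
                               {aa: 100.0 for aa in s1.required_aa})
        d = rhs(state, [s1])
        assert d.biomass[s1.name] == pytest.approx(s1.mu_max * 1e7, rel=0.01)

    def test_growth_coupled_secretion_variant(self):
        a, b = symmetric_pair(1e-9, 5e-10)
        state = CommunityState(0.0, {"A": 1e7, "B": 1e7}, 5.0,
                               {"aa1": 3.0, "aa2": 3.0})
        d_ab = rhs(state, (a, b), coupling="abundance")
        d_gr = rhs(state, (a, b), coupling="growth")
        # abundance coupling secretes alpha*N; growth coupling alpha*dN
        mu_b = d_gr.biomass["B"] / 1e7
        assert d_ab.aa_mM["aa1"] - d_gr.aa_mM["aa1"] == pytest.approx(
            1e-9 * 1e7 * (1 - mu_b), rel=1e-6
        )
        with pytest.raises(ValueError):
            rhs(state, (a, b), coupling="osmosis")


class TestSimulate:
    def test_monoculture_glucose_mass_balance(self):
        s = monoculture_strain()
        med = medium_for_scenario("all")
        init = initial_state([s], med, {s.name: N0_55})
        traj = simulate(init, [s], 48.0)
        n_end = traj.biomass[s.name].iloc[-1]
        expected = N0_55 + s.yield_glc * (med.glucose_g_l - traj.glucose_g_l[-1])
        assert n_end == pytest.approx(expected, rel=0.01)
        assert traj.glucose_g_l[-1] <= med.glucose_g_l

    def test_aa_balance_abundance_coupling(self):
        # produced (α·∫N dt) − consumed (β·ΔN) must equal the pool change
        strains = default_strains()
        med = medium_for_scenario("none")
        init = initial_state(strains, med, {s.name: N0_55 for s in strains})
        traj = simulate(init, strains, 48.0)
        for aa in traj.aa_mM.columns:
            produced = consumed = 0.0
            for s in strains:
                N = traj.biomass[s.name].to_numpy()
                if aa in s.alpha:
                    produced += s.alpha[aa] * np.trapezoid(N, traj.time_h)
                if aa in s.beta:
                    consumed += s.beta[aa] * (N[-1] - N[0])
            dA = traj.aa_mM[aa].iloc[-1] - traj.aa_mM[aa].iloc[0]
            assert produced - consumed == pytest.approx(dA, rel=0.01, abs=1e-6)

    def test_aa_balance_growth_coupling(self):
        # with growth-coupled secretion the production integral is α·ΔN
        a, b = symmetric_pair(1e-9, 5e-10)
        med = MediumCondition(supplemented_aa_mM={}, trace_aa_mM=5e-3)
        init = initial_state((a, b), med, {"A": N0_55, "B": N0_55})
        traj = simulate(init, (a, b), 48.0, coupling="growth")
        dN_a = traj.biomass["A"].iloc[-1] - traj.biomass["A"].iloc[0]
        dN_b = traj.biomass["B"].iloc[-1] - traj.biomass["B"].iloc[0]
        dA1 = traj.aa_mM["aa1"].iloc[-1] - traj.aa_mM["aa1"].iloc[0]
        assert 1e-9 * dN_a - 5e-10 * dN_b == pytest.approx(dA1, rel=0.01)

    def test_monoculture_exponential_phase(self):
        # before glucose depletion growth matches the saturated closed form
        s = monoculture_strain()
        med = medium_for_scenario("all")
        n0 = 1e6  # small inoculum keeps glucose ~constant over many folds
        init = initial_state([s], med, {s.name: n0})
        traj = simulate(init, [s], 12.0, dt_h=0.05)
        mu_ref = (
            s.mu_max
            * med.glucose_g_l / (s.k_glc + med.glucose_g_l)
            * (3.0 / (3.0 + s.k_for("isoleucine"))) ** 3
        )
        mask = traj.glucose_g_l > 0.995 * med.glucose_g_l
        i = np.nonzero(mask)[0][-1]
        expected = n0 * np.exp(mu_ref * traj.time_h[i])
        assert traj.biomass[s.name].iloc[i] == pytest.approx(expected, rel=0.01)

    def test_no_exchange_no_growth(self):
        a, b = symmetric_pair(0.0, 5e-10)
        med = MediumCondition(supplemented_aa_mM={}, trace_aa_mM=0.0)
        init = initial_state((a, b), med, {"A": N0_55, "B": N0_55})
        traj = simulate(init, (a, b), 24.0)
        assert np.allclose(traj.fold_change.iloc[-1], 1.0, atol=1e-6)

    def test_biculture_grows_without_supplementation(self):
        strains = default_strains()
        med = medium_for_scenario("none")
        init = initial_state(strains, med, {s.name: N0_55 for s in strains})
        traj = simulate(init, strains, 48.0)
        assert (traj.fold_change.iloc[-1] > 1.0).all()

    def test_nonnegative_states_and_step_refinement(self):
        strains = default_strains()
        med = medium_for_scenario("isoleucine")
        init = initial_state(strains, med, {s.name: N0_55 for s in strains})
        coarse = simulate(init, strains, 24.0, dt_h=1.0 / 6.0)
        fine = simulate(init, strains, 24.0, dt_h=1.0 / 60.0)
        assert (coarse.biomass.to_numpy() >= 0).all()
        assert (coarse.aa_mM.to_numpy() >= 0).all()
        for s in strains:
            a = coarse.biomass[s.name].iloc[-1]
            b = fine.biomass[s.name].iloc[-1]
            assert a == pytest.approx(b, rel=1e-3)

    def test_label_swap_symmetry(self):
        a, b = symmetric_pair(1e-9, 5e-10)
        med = MediumCondition(supplemented_aa_mM={})
        init = initial_state((a, b), med, {"A": 2e7, "B": 5e6})
        traj = simulate(init, (a, b), 24.0)
        init_sw = initial_state((a, b), med, {"A": 5e6, "B": 2e7})
        traj_sw = simulate(init_sw, (a, b), 24.0)
        assert np.allclose(traj.biomass["A"], traj_sw.biomass["B"], rtol=1e-6)
        assert np.allclose(traj.biomass["B"], traj_sw.biomass["A"], rtol=1e-6)

    def test_aa_loss_channel_drains_pool(self):
        s = monoculture_strain()
        med = medium_for_scenario("all")
        init = initial_state([s], med, {s.name: 1e3})  # negligible biomass
        traj = simulate(init, [s], 10.0, aa_loss_per_h=0.2)
        # pools decay ~ exp(-0.2 t) when consumption is negligible
        a0 = init.aa_mM["valine"]
        assert traj.aa_mM["valine"].iloc[-1] == pytest.approx(
            a0 * np.exp(-0.2 * 10.0), rel=0.01
        )

    def test_fold_change_starts_at_one(self):
        strains = default_strains()
        med = medium_for_scenario("all")
        init = initial_state(strains, med, {s.name: N0_55 for s in strains})
        traj = simulate(init, strains, 6.0)
        assert np.allclose(traj.fold_change.iloc[0], 1.0)

    def test_trajectory_long_format(self):
        s = monoculture_strain()
        med = medium_for_scenario("all")
        init = initial_state([s], med, {s.name: N0_55})
        traj = simulate(init, [s], 2.0)
        frame = trajectory_to_frame(traj)
        assert set(frame.columns) == {"time_h", "variable", "value"}
        assert f"biomass:{s.name}" in set(frame["variable"])


class TestSweepAndClassify:
    def test_fixed_density_sweep_is_size_invariant(self):
        s = monoculture_strain()
        med = medium_for_scenario("all")
        table = sweep_density((55.0, 100.0, 150.0), "fixed_density", 5.0, [s],
                              med, t_end_h=24.0)
        ks = table["K"].to_numpy()
        assert np.allclose(ks, ks[0], rtol=1e-6)
        assert np.allclose(table["r"], table["r"].iloc[0], rtol=1e-6)

    def test_fixed_lambda_capacity_grows_with_diameter(self):
        s = monoculture_strain()
        med = medium_for_scenario("all")
        table = sweep_density((55.0, 100.0, 150.0), "fixed_lambda", 5.0, [s],
                              med, t_end_h=48.0)
        ks = table.sort_values("diameter_um")["K"].to_numpy()
        assert np.all(np.diff(ks) > 0)
        # 55 μm capacity ≈ (yield·G0)/N0 = 4e9/5.74e7 ≈ 70 fold
        assert ks[0] == pytest.approx(4e9 / N0_55, rel=0.05)

    def test_sweep_input_validation(self):
        s = monoculture_strain()
        med = medium_for_scenario("all")
        with pytest.raises(ValueError):
            sweep_density((55.0,), "fixed_lambda", 5.0, [s], med)
        with pytest.raises(ValueError):
            sweep_density((55.0, 100.0), "fixed_mu", 5.0, [s], med)

    def test_constant_table_classifies_none(self):
        table = pd.DataFrame({
            "diameter_um": [55, 55, 100, 100, 150, 150],
            "strain": ["A", "B"] * 3,
            "K": [50.0] * 6, "r": [0.8] * 6, "tau": [2.0] * 6,
            "rss": [0.0] * 6, "converged": [True] * 6,
        })
        assert classify_trend(table).label == "none"

    def test_too_few_densities_rejected(self):
        table = pd.DataFrame({
            "diameter_um": [55, 100], "strain": ["A", "A"],
            "K": [10, 20], "r": [0.8, 0.8], "tau": [1, 1],
            "rss": [0, 0], "converged": [True, True],
        })
        with pytest.raises(ValueError):
            classify_trend(table)

    def test_partial_fit_failure_reported(self):
        table = pd.DataFrame({
            "diameter_um": [55, 100, 150], "strain": ["A"] * 3,
            "K": [10, 20, 1], "r": [0.8, 0.8, 0.0], "tau": [1, 1, 0],
            "rss": [0, 0, 0], "converged": [True, True, False],
        })
        with pytest.raises(ValueError, match="150"):
            classify_trend(table)

    def test_low_secretion_lengthens_lag_type1(self):
        # weak secretion: the pool builds at a rate ∝ N0, so dilution
        # stretches the lag while the post-bootstrap rate stays put
        med = medium_for_scenario("none")
        strains = default_strains(alpha_s1=2e-10, alpha_s2=2e-10,
                                  beta=8e-10, secretion_scale={})
        table = sweep_density((55.0, 75.0, 100.0), "fixed_lambda", 5.0,
                              strains, med, t_end_h=48.0)
        cls = classify_trend(table)
        assert cls.label == "Type1"
        assert cls.delta_tau_rel > 0.25
        assert abs(cls.delta_r_rel) < 0.10

    def test_high_requirement_slows_rate_type2(self):
        # high requirement caps growth at the slow exchange-limited rate;
        # dilute conditions overflow the observation window, so the apparent
        # rate declines while the apparent lag stalls
        med = medium_for_scenario("none")
        strains = default_strains(alpha_s1=2e-9, alpha_s2=2e-9,
                                  beta=1.6e-8, secretion_scale={})
        table = sweep_density((55.0, 75.0, 100.0), "fixed_lambda", 5.0,
                              strains, med, t_end_h=48.0)
        cls = classify_trend(table)
        assert cls.label == "Type2"
        assert cls.delta_r_rel < -0.15
        assert abs(cls.delta_tau_rel) < 0.25
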