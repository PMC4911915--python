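"""Kinetic model construction, simulation, steady states and their oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from selhier.features import TranscriptFeatures
from selhier.models import (
    POLYA_LEVELS,
    ModelError,
    RateParameters,
    SeCondition,
    SteadyStateError,
    build_model,
    elongation_rates,
    m1b_steady_state_totals,
    model1_steady_state_closed_form,
    se_to_trna_level,
    simulate_timecourse,
    solve_steady_state,
    steady_state_total,
)

from conftest import random_features, random_positive_params


class TestSeMap:
    def test_basal_level_at_zero(self):
        assert se_to_trna_level(0, 0.1, 1.0, 10) == pytest.approx(0.1)

    def test_hand_evaluated_midpoint(self):
        # c = k_half gives s0 + smax/2
        assert se_to_trna_level(10, 0.1, 1.0, 10) == pytest.approx(0.6)

    def test_saturation_limit(self):
        assert se_to_trna_level(1e9, 0.1, 1.0, 10) == pytest.approx(1.1, rel=1e-6)

    @given(
        c1=st.floats(0, 1e3),
        c2=st.floats(0, 1e3),
        s0=st.floats(0.01, 1),
        smax=st.floats(0.1, 5),
        k_half=st.floats(0.1, 100),
    )
    def test_monotone_in_dose(self, c1, c2, s0, smax, k_half):
        lo, hi = sorted((c1, c2))
        assert se_to_trna_level(lo, s0, smax, k_half) <= se_to_trna_level(hi, s0, smax, k_half)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            se_to_trna_level(-1, 0.1, 1, 10)
        with pytest.raises(ValueError):
            se_to_trna_level(1, 0.1, 1, 0)


class TestBuildModel:
    def test_m1_network_shape(self, features, params):
        spec = build_model("M1", features, params, SeCondition(0, 0.5))
        assert spec.n_species == 5
        # 7 core reactions + 5 background decays
        assert len(spec.reactions) == 12

    def test_m2_adds_drop_off(self, features, params):
        spec = build_model("M2", features, params.replace(k_drop=2.0), SeCondition(0, 0.5))
        assert spec.n_species == 5
        assert len(spec.reactions) == 13
        assert any(r.name == "drop_off" for r in spec.reactions)

    def test_m3_replicates_states_over_tail_levels(self, features, params):
        spec = build_model("M3", features, params.replace(k_drop=2.0), SeCondition(0, 0.5))
        assert spec.n_species == 5 * len(POLYA_LEVELS) == 35

    def test_m1b_adds_shared_pool_species(self, panel_truth):
        panel, truth = panel_truth
        ps = [g.params.replace(k_drop=0.0) for g in truth.genes]
        spec = build_model("M1B", panel, ps, SeCondition(0, 0.5), pool_total=5.0)
        assert spec.n_species == 11 * 5 + 1 == 56

    def test_invalid_constructions_rejected(self, features, params):
        with pytest.raises(ModelError):
            build_model("M9", features, params, SeCondition(0, 0.5))
        with pytest.raises(ModelError):
            build_model("M1", features, params.replace(k_drop=1.0), SeCondition(0, 0.5))
        with pytest.raises(ModelError):
            build_model("M1B", [features], [params], SeCondition(0, 0.5), pool_total=1.0)
        with pytest.raises(ModelError):
            build_model(
                "M1B",
                [features, TranscriptFeatures("B", 50, 20, 0)],
                [params, params],
                SeCondition(0, 0.5),
            )


class TestSimulate:
    def test_pure_source_grows_linearly(self, features):
        p = RateParameters(v_txn=3.0, k_init=0, r_elong=1e-9, k_bind=0, k_nmd=0, k_sec=0, d_bg=0)
        spec = build_model("M1", features, p, SeCondition(0, 0.5))
        sim = simulate_timecourse(spec, t_end=10, rtol=1e-10, atol=1e-12)
        assert sim.converged
        total = sim.total_mrna["GENE"]
        assert total[-1] == pytest.approx(3.0 * 10, rel=1e-6)

    def test_uniform_decay_is_exponential(self, features):
        p = RateParameters(v_txn=0, k_init=0, r_elong=1e-9, k_bind=0, k_nmd=0, k_sec=0, d_bg=0.5)
        spec = build_model("M1", features, p, SeCondition(0, 0.5))
        init = np.array([2.0, 1.0, 0.5, 0.25, 0.25])
        sim = simulate_timecourse(spec, init=init, t_end=4.0, rtol=1e-10, atol=1e-12)
        total = sim.total_mrna["GENE"]
        assert total[-1] == pytest.approx(4.0 * np.exp(-0.5 * 4.0), rel=1e-6)

    def test_long_time_reaches_closed_form_steady_state(self, features, params):
        spec = build_model("M1", features, params, SeCondition(10, 0.6))
        sim = simulate_timecourse(spec, t_end=400.0, rtol=1e-10, atol=1e-12)
        expected = model1_steady_state_closed_form(params, features, 0.6)
        assert sim.total_mrna["GENE"][-1] == pytest.approx(expected, rel=1e-6)

    def test_trajectories_stay_non_negative(self, features):
        rng = np.random.default_rng(7)
        for _ in range(5):
            p = random_positive_params(rng)
            spec = build_model("M1", features, p, SeCondition(0, 0.5))
            sim = simulate_timecourse(spec, t_end=50.0, atol=1e-10)
            assert sim.converged
            assert sim.states.min() >= -1e-10

    def test_bad_init_rejected(self, features, params):
        spec = build_model("M1", features, params, SeCondition(0, 0.5))
        with pytest.raises(ValueError):
            simulate_timecourse(spec, init=np.full(5, -1.0))
        with pytest.raises(ValueError):
            simulate_timecourse(spec, t_end=0)


class TestSteadyState:
    def test_linear_solve_matches_closed_form(self, features):
        rng = np.random.default_rng(11)
        for _ in range(30):
            p = random_positive_params(rng)
            s = 10 ** rng.uniform(-1.5, 0.5)
            spec = build_model("M1", features, p, SeCondition(0, s))
            assert solve_steady_state(spec).total == pytest.approx(
                model1_steady_state_closed_form(p, features, s), rel=1e-10
            )

    def test_m2_matches_independent_balance_oracle(self):
        """Brute-force oracle: write the five balance equations directly as a
        linear system, independently of the reaction-network assembly."""
        rng = np.random.default_rng(13)
        for _ in range(20):
            p = random_positive_params(rng, with_drop=True)
            f = random_features(rng)
            s = 10 ** rng.uniform(-1.5, 0.5)
            k_el1, k_el2 = elongation_rates(p, f)
            kb = p.k_bind * s
            d = p.d_bg
            A = np.array(
                [
                    [-(p.k_init + d), 0, p.k_drop, 0, k_el2],
                    [p.k_init, -(k_el1 + d), 0, 0, 0],
                    [0, k_el1, -(p.k_nmd + p.k_drop + kb + d), 0, 0],
                    [0, 0, kb, -(p.k_sec + d), 0],
                    [0, 0, 0, p.k_sec, -(k_el2 + d)],
                ]
            )
            b = np.array([p.v_txn, 0, 0, 0, 0])
            oracle_total = np.linalg.solve(A, -b).sum()
            assert steady_state_total("M2", p, f, s) == pytest.approx(oracle_total, rel=1e-10)

    def test_m3_chain_matches_generic_linear_solve(self, features):
        rng = np.random.default_rng(17)
        for _ in range(10):
            p = random_positive_params(rng, with_drop=True)
            s = 10 ** rng.uniform(-1.5, 0.5)
            spec = build_model("M3", features, p, SeCondition(0, s))
            assert solve_steady_state(spec).total == pytest.approx(
                steady_state_total("M3", p, features, s), rel=1e-10
            )

    def test_no_nmd_total_is_transcription_over_decay(self, features, params):
        p = params.replace(k_nmd=0.0)
        for s in (0.1, 0.6, 1.1):
            assert model1_steady_state_closed_form(p, features, s) == pytest.approx(
                p.v_txn / p.d_bg, rel=1e-12
            )

    def test_added_nmd_sink_lowers_the_pool(self, features, params):
        heavy = params.replace(k_nmd=500.0, k_sec=0.0)
        assert model1_steady_state_closed_form(heavy, features, 0.5) < params.v_txn / params.d_bg

    def test_singular_system_raises_informative_error(self, features):
        p = RateParameters(k_nmd=0.0, d_bg=0.0)
        spec = build_model("M1", features, p, SeCondition(0, 0.5))
        with pytest.raises(SteadyStateError, match="sink"):
            solve_steady_state(spec)
        with pytest.raises(ModelError):
            model1_steady_state_closed_form(p, features, 0.5)


class TestMonotonicityAndInverse:
    def test_m1_m2_totals_non_decreasing_in_trna(self, features):
        rng = np.random.default_rng(19)
        s_grid = np.linspace(0.01, 2.0, 25)
        for model_id, with_drop in (("M1", False), ("M2", True)):
            for _ in range(40):
                p = random_positive_params(rng, with_drop=with_drop)
                totals = [steady_state_total(model_id, p, features, s) for s in s_grid]
                assert np.all(np.diff(totals) >= -1e-10 * max(totals))

    def test_m3_inverse_response_attainable(self, features, params):
        """With frequent drop-off, more tRNA-Sec shortens poly(A) tails faster
        and the steady-state pool strictly decreases with selenium."""
        p = params.replace(k_nmd=0.8, k_drop=16.0, k_bind=15.0, k_sec=9.0)
        s_grid = np.linspace(0.1, 1.1, 15)
        totals = [steady_state_total("M3", p, features, s) for s in s_grid]
        assert np.all(np.diff(totals) < 0)


class TestM1B:
    def test_pool_conservation_along_trajectory(self, features, params):
        other = TranscriptFeatures("B", 220, 30, 90)
        spec = build_model(
            "M1B", [features, other], [params, params.replace(k_bind=20.0)],
            SeCondition(0, 0.5), pool_total=2.0,
        )
        sim = simulate_timecourse(spec, t_end=60.0, rtol=1e-10, atol=1e-12)
        assert sim.converged
        i_t = spec.species_index("tRNA")
        i_r2 = [spec.species_index(s) for s in spec.species if s.endswith(":R2")]
        pool = sim.states[i_t] + sim.states[i_r2].sum(axis=0)
        assert np.abs(pool - 2.0).max() / 2.0 < 1e-9

    def test_steady_state_agrees_with_long_simulation(self, features, params):
        other = TranscriptFeatures("B", 220, 30, 90)
        spec = build_model(
            "M1B", [features, other], [params, params], SeCondition(0, 0.5), pool_total=1.5
        )
        ss = solve_steady_state(spec)
        assert ss.residual_norm < 1e-10
        sim = simulate_timecourse(spec, t_end=400.0, rtol=1e-11, atol=1e-13)
        np.testing.assert_allclose(sim.states[:, -1], ss.values, rtol=1e-6)

    def test_reduces_to_m1_for_large_pool(self, panel_truth):
        panel, truth = panel_truth
        ps = [g.params.replace(k_drop=0.0) for g in truth.genes]
        errors = []
        for pool in (10.0, 100.0, 1000.0):
            coupled = m1b_steady_state_totals(ps, panel, pool)
            uncoupled = {
                f.gene_id: steady_state_total("M1", p, f, pool) for f, p in zip(panel, ps)
            }
            errors.append(
                max(abs(coupled[g] - uncoupled[g]) / uncoupled[g] for g in uncoupled)
            )
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 1e-2
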