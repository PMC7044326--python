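"""Gated-accumulator agent: update rules, choice model, simulation, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histgate import (
    DynamicParams,
    LatentState,
    TaskConfig,
    choice_probability,
    compute_trace,
    decompose_repeating_bias,
    fit_dynamic_model,
    generate_stimulus_session,
    simulate_agent,
    update_latents,
)
from histgate.psychometrics import alternation_pattern, repetition_pattern


class TestUpdateLatents:
    def test_error_extinguishes_gate(self):
        params = DynamicParams(delta_C_minus=-1.0)
        state = LatentState(0.0, 0.5, 0.8)
        new = update_latents(state, 1, "error", "correct", 1, params)
        assert new.c_T == 0.0

    def test_correct_fully_recovers_gate(self):
        params = DynamicParams(delta_C_plus=1.0)
        state = LatentState(0.0, 0.5, 0.0)
        new = update_latents(state, 1, "correct", "error", 1, params)
        assert new.c_T == 1.0

    def test_transition_leak_arithmetic(self):
        # error repetition with prev correct: leak λ_T^- applies, Δ_T^{+-} = 0
        params = DynamicParams(lambda_T_minus=0.2, delta_T_pm=0.0)
        state = LatentState(0.0, 0.6, 1.0)
        new = update_latents(state, 1, "error", "correct", 1, params)
        assert new.z_T == pytest.approx(0.48)

    def test_lateral_update(self):
        params = DynamicParams(delta_L_plus=0.1, lambda_L_plus=0.5)
        new = update_latents(LatentState(0.4, 0.0, 1.0), -1, "correct", None, None, params)
        assert new.z_L == pytest.approx(0.5 * 0.4 - 0.1)

    def test_first_trial_skips_transition_update(self):
        params = DynamicParams()
        new = update_latents(LatentState(0.0, 0.3, 1.0), 1, "correct", None, None, params)
        assert new.z_T == 0.3

    @settings(derandomize=True, max_examples=50)
    @given(
        dc_plus=st.floats(-1, 1), dc_minus=st.floats(-1, 1),
        seq=st.lists(st.tuples(st.sampled_from([-1, 1]), st.booleans()), min_size=1, max_size=30),
    )
    def test_gate_stays_bounded(self, dc_plus, dc_minus, seq):
        """c_T remains in [0, 1] for any updates and any trial sequence."""
        params = DynamicParams(delta_C_plus=dc_plus, delta_C_minus=dc_minus)
        state = LatentState(0.0, 0.0, 1.0)
        prev_out = None
        prev_resp = None
        for resp, correct in seq:
            outcome = "correct" if correct else "error"
            trans = None if prev_resp is None else prev_resp * resp
            state = update_latents(state, resp, outcome, prev_out, trans, params)
            assert 0.0 <= state.c_T <= 1.0
            prev_out, prev_resp = outcome, resp


class TestChoiceProbability:
    def test_symmetric_point(self):
        p = choice_probability(LatentState(0, 0, 1), 0.0, 0, DynamicParams())
        assert p == pytest.approx(0.5)

    def test_closed_gate_blocks_transition_evidence(self):
        params = DynamicParams()
        p1 = choice_probability(LatentState(0, 5.0, 0.0), 0.0, 1, params)
        p2 = choice_probability(LatentState(0, -5.0, 0.0), 0.0, 1, params)
        assert p1 == pytest.approx(p2) == pytest.approx(0.5)

    def test_lapse_ceiling(self):
        params = DynamicParams(lapse_R=0.1, lapse_L=0.1)
        p = choice_probability(LatentState(0, 0, 1), 1e6, 0, params)
        assert p == pytest.approx(0.9)


class TestSimulation:
    def test_post_error_transition_bias_resets(self, gating_session):
        post_error = (gating_session["prev_outcome"] == "error").to_numpy()
        assert np.abs(gating_session.loc[post_error, "gamma_T"]).max() == 0.0

    def test_evidence_retained_through_errors(self, gating_session):
        """With λ_T^- < 1 the transition evidence z_T survives errors even
        though the bias γ^T is gated off."""
        err_prev = (gating_session["prev_outcome"] == "error").to_numpy()
        z = np.abs(gating_session.loc[err_prev, "z_T"])
        assert (z > 0.05).mean() > 0.5

    def test_stimulus_only_accuracy_matches_probit(self, task_config):
        stim = generate_stimulus_session(task_config, 20_000, seed=31)
        sim = simulate_agent(stim, DynamicParams.stimulus_only(), seed=32)
        acc = (sim["response"] == sim["category"]).mean()
        p = sim["p_right"].to_numpy()
        expected = np.where(sim["category"] == 1, p, 1 - p).mean()
        assert acc == pytest.approx(expected, abs=0.01)

    def test_trace_recomputation_matches_simulation(self, small_session):
        trace = compute_trace(small_session, DynamicParams.gating_defaults())
        assert np.allclose(trace.z_T, small_session["z_T"], atol=0)
        assert np.allclose(trace.gamma_T, small_session["gamma_T"], atol=0)
        assert np.allclose(trace.p_right, small_session["p_right"], atol=0)

    def test_complete_reset_erases_evidence_after_error(self, task_config):
        stim = generate_stimulus_session(task_config, 5_000, seed=33)
        sim = simulate_agent(stim, DynamicParams.complete_reset_defaults(), seed=34)
        err_prev = (sim["prev_outcome"] == "error").to_numpy()
        # λ_T^- = 1: z_T after an error keeps nothing of its pre-error value;
        # it equals the single update from the error transition (Δ = 0 here)
        assert np.abs(sim.loc[err_prev, "z_T"]).max() == 0.0


class TestFitting:
    def test_empty_session_rejected(self, small_session):
        with pytest.raises(ValueError):
            fit_dynamic_model(small_session.iloc[:0])

    def test_smoke_fit_improves_on_start(self, small_session):
        fit = fit_dynamic_model(small_session, n_starts=2, seed=1)
        assert np.isfinite(fit.log_posterior)
        assert fit.log_likelihood > -len(small_session) * np.log(2)  # beats coin flipping


class TestBiasDecomposition:
    def test_zero_history_weights_give_zero_contributions(self, task_config):
        stim = generate_stimulus_session(task_config, 3_000, seed=35)
        sim = simulate_agent(stim, DynamicParams.stimulus_only(), seed=36)
        lat, trans, total = decompose_repeating_bias(sim, repetition_pattern(1))
        assert lat == 0.0 and trans == 0.0 and total == 0.0

    def test_repetitions_align_contributions_alternations_cancel_lateral(self, gating_session):
        lat_rep, trans_rep, _ = decompose_repeating_bias(gating_session, repetition_pattern(3))
        lat_alt, trans_alt, _ = decompose_repeating_bias(gating_session, alternation_pattern(3))
        # correct repetitions: lateral and transition contributions share sign
        assert lat_rep > 0 and trans_rep > 0
        # correct alternations: transition pushes to alternate, lateral ~ cancels
        assert trans_alt < 0
        assert abs(lat_alt) < 0.3 * abs(trans_alt)
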