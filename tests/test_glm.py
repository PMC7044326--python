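"""History-GLM design matrix, likelihood, fitting and model comparison."""

import numpy as np
import pytest
from scipy.special import ndtr

from histgate import (
    DynamicParams,
    TaskConfig,
    build_design_matrix,
    compare_models,
    fit_glm,
    generate_stimulus_session,
    predict_glm,
    simulate_agent,
)

from conftest import make_manual_session


def transition_values(design, row, subtype, lags):
    """T^{o,q}_{t−k} recovered from the stored (projected) columns."""
    r_prev = design.response[row - 1]
    return [
        design.X[row, design.column_index(f"transition_{subtype}_lag{k}")] / r_prev
        for k in lags
    ]


class TestDesignMatrix:
    def test_correct_repetition_run_coding(self):
        # choices R+ R+ R+ L+ then a probe trial: transitions Rep,Rep,Alt all ++
        t = make_manual_session([1, 1, 1, -1, 1], [1, 1, 1, -1, 1])
        d = build_design_matrix(t)
        assert transition_values(d, 4, "pp", [3, 2, 1]) == [1.0, 1.0, -1.0]

    def test_error_breaks_pp_transition(self):
        # R+ R+ R+ R-: the last transition is type +-, so T^{++} at lag 1 is 0
        t = make_manual_session([1, 1, 1, 1, 1], [1, 1, 1, -1, 1])
        d = build_design_matrix(t)
        assert transition_values(d, 4, "pp", [1]) == [0.0]
        assert transition_values(d, 4, "pm", [1]) == [1.0]

    def test_error_response_coding(self):
        # an error at t-1 sets r^+ to 0 and r^- to the signed response
        t = make_manual_session([1, -1, 1], [1, 1, 1])
        d = build_design_matrix(t)
        assert d.X[2, d.column_index("lateral_plus_lag1")] == 0.0
        assert d.X[2, d.column_index("lateral_minus_lag1")] == -1.0

    def test_lateral_exclusivity_invariant(self, small_session):
        d = build_design_matrix(small_session)
        for k in range(1, 6):
            plus = d.X[:, d.column_index(f"lateral_plus_lag{k}")]
            minus = d.X[:, d.column_index(f"lateral_minus_lag{k}")]
            assert not np.any((plus != 0) & (minus != 0))

    def test_history_does_not_cross_sessions(self, small_session):
        two = small_session.copy()
        half = len(two) // 2
        two.loc[two.index[half:], "session_id"] = "s2"
        d = build_design_matrix(two)
        row = half  # first trial of the second session
        hist = [i for i, c in enumerate(d.columns) if c.family != "stimulus" and c.lag > 0]
        assert np.all(d.X[row, hist] == 0.0)
        assert not d.fit_mask[row]

    def test_likelihood_matches_brute_force(self):
        """Exact oracle: hand-enumerated regressors and likelihood on a short
        session with two lags reproduce the pipeline's values."""
        rng = np.random.default_rng(9)
        resp = rng.choice([-1, 1], size=20)
        cat = rng.choice([-1, 1], size=20)
        ev = rng.choice([-0.48, 0.0, 0.48], size=20)
        t = make_manual_session(resp, cat, evidence=ev, n_frames=2)
        d = build_design_matrix(t, n_lags=2, pooled_tail_to=2)
        correct = resp == cat
        r_plus = np.where(correct, resp, 0)
        r_minus = np.where(~correct, resp, 0)
        frames = np.column_stack([ev / 2, ev / 2])
        s_sum = frames.sum(axis=1)
        for row in range(2, 20):
            expected = {"intercept": 1.0, "stim_f1": ev[row] / 2, "stim_f2": ev[row] / 2}
            for k in (1, 2):
                expected[f"aftereffect_lag{k}"] = s_sum[row - k]
                expected[f"lateral_plus_lag{k}"] = r_plus[row - k]
                expected[f"lateral_minus_lag{k}"] = r_minus[row - k]
                for oq, (a, b) in {
                    "pp": (r_plus, r_plus), "pm": (r_plus, r_minus),
                    "mp": (r_minus, r_plus), "mm": (r_minus, r_minus),
                }.items():
                    tv = a[row - k - 1] * b[row - k] if row - k - 1 >= 0 else 0.0
                    expected[f"transition_{oq}_lag{k}"] = tv * resp[row - 1]
            for name, val in expected.items():
                assert d.X[row, d.column_index(name)] == pytest.approx(val), (row, name)
        # likelihood at arbitrary weights equals the direct computation
        w = rng.normal(0, 0.3, size=len(d.columns))
        lapse_r, lapse_l = 0.05, 0.08
        p = lapse_r + (1 - lapse_r - lapse_l) * ndtr(d.X @ w)
        v = (resp == 1).astype(float)
        manual = 0.0
        for row in range(20):
            if not d.fit_mask[row]:
                continue
            y_row = sum(
                w[i] * d.X[row, i] for i in range(len(w))
            )
            p_row = lapse_r + (1 - lapse_r - lapse_l) * ndtr(y_row)
            manual += np.log(p_row if v[row] else 1 - p_row)
        vectorized = np.sum(
            np.where(v[d.fit_mask] == 1, np.log(p[d.fit_mask]), np.log(1 - p[d.fit_mask]))
        )
        assert vectorized == pytest.approx(manual, rel=1e-12)


@pytest.fixture(scope="module")
def null_fit():
    cfg = TaskConfig()
    stim = generate_stimulus_session(cfg, 20_000, seed=50)
    sim = simulate_agent(stim, DynamicParams.stimulus_only(), seed=51)
    design = build_design_matrix(sim)
    return fit_glm(design, "all")


class TestFit:
    def test_stimulus_only_agent_null_kernels(self, null_fit):
        fit = null_fit
        for c, w, s in zip(fit.columns, fit.weights, fit.se):
            if c.family in ("lateral", "transition") and not np.isnan(w):
                assert abs(w) < 3.5 * s, c.name
        stim_w = [fit.weight(f"stim_f{f}") for f in range(1, 9)]
        assert all(w > 0.2 for w in stim_w)

    def test_left_right_symmetry(self, task_config):
        """Relabeling left/right negates the fixed bias and leaves the
        history kernels invariant."""
        stim = generate_stimulus_session(task_config, 10_000, seed=52)
        sim = simulate_agent(stim, DynamicParams(fixed_bias=0.3), seed=53)
        mirrored = sim.copy()
        for col in ("category", "response", "prev_response"):
            mirrored[col] = -mirrored[col]
        for col in [c for c in sim.columns if c.startswith("frame_")] + ["evidence"]:
            mirrored[col] = -mirrored[col]
        f1 = fit_glm(build_design_matrix(sim), "all", compute_se=False)
        f2 = fit_glm(build_design_matrix(mirrored), "all", compute_se=False)
        assert f1.weight("intercept") == pytest.approx(-f2.weight("intercept"), abs=5e-3)
        k1 = f1.kernel("transition", "pp")["weight"].to_numpy()
        k2 = f2.kernel("transition", "pp")["weight"].to_numpy()
        assert np.allclose(k1, k2, atol=5e-3, equal_nan=True)

    def test_predict_bounds_and_null_point(self, small_session):
        design = build_design_matrix(small_session)
        fit = fit_glm(design, "all", compute_se=False)
        zero = fit
        zero = type(fit)(
            columns=fit.columns, weights=np.zeros_like(fit.weights), se=fit.se,
            lapse_R=0.0, lapse_L=0.0, condition="all", loglik=0.0, n_trials=1,
            n_params=1, converged=True,
        )
        assert np.allclose(predict_glm(zero, design), 0.5)
        lapsy = type(fit)(
            columns=fit.columns, weights=np.nan_to_num(fit.weights) * 50, se=fit.se,
            lapse_R=0.07, lapse_L=0.11, condition="all", loglik=0.0, n_trials=1,
            n_params=1, converged=True,
        )
        p = predict_glm(lapsy, design)
        assert p.min() >= 0.07 - 1e-12 and p.max() <= 1 - 0.11 + 1e-12

    def test_split_by_outcome_beats_pooled_on_heldout_data(self, task_config):
        """The outcome-split GLM generalizes better than the pooled fit on
        gating-agent data: a single kernel set cannot express the post-error
        flattening of the transition weights at lags >= 2."""
        train = simulate_agent(
            generate_stimulus_session(task_config, 50_000, seed=42),
            DynamicParams.gating_defaults(), seed=43,
        )
        test = simulate_agent(
            generate_stimulus_session(task_config, 50_000, seed=142),
            DynamicParams.gating_defaults(), seed=143,
        )
        design, heldout = build_design_matrix(train), build_design_matrix(test)
        pooled = fit_glm(design, "all", compute_se=False)
        split = [
            fit_glm(design, "after_correct", compute_se=False),
            fit_glm(design, "after_error", compute_se=False),
        ]
        table = compare_models(
            {"pooled": [pooled], "split": split}, design, heldout=heldout
        ).set_index("model")
        assert table.loc["split", "heldout_loglik"] > table.loc["pooled", "heldout_loglik"]
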