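import numpy as np
import pandas as pd
import pytest

from histgate import DynamicParams, TaskConfig, generate_stimulus_session, simulate_agent


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def gating_session(task_config):
    """20k-trial session simulated from the reference gating agent."""
    stim = generate_stimulus_session(task_config, 20_000, seed=42)
    return simulate_agent(stim, DynamicParams.gating_defaults(), seed=43)


@pytest.fixture(scope="session")
def small_session(task_config):
    stim = generate_stimulus_session(task_config, 600, seed=7)
    return simulate_agent(stim, DynamicParams.gating_defaults(), seed=8)


def make_manual_session(responses, categories, evidence=None, n_frames=2, session_id="s1"):
    """Hand-built session with frames equal to evidence (for design tests)."""
    n = len(responses)
    responses = np.asarray(responses, dtype=float)
    categories = np.asarray(categories, dtype=int)
    evidence = np.zeros(n) if evidence is None else np.asarray(evidence, dtype=float)
    table = pd.DataFrame(
        {
            "session_id": session_id,
            "trial_index": np.arange(1, n + 1),
            "block": "repeating",
            "category": categories,
            "strength": np.abs(evidence),
            "evidence": evidence,
        }
    )
    for f in range(n_frames):
        table[f"frame_{f + 1}"] = evidence / n_frames
    table["response"] = responses
    table["outcome"] = np.where(
        np.isnan(responses), None, np.where(responses == categories, "correct", "error")
    )
    table["prev_response"] = table.groupby("session_id")["response"].shift(1)
    table["prev_outcome"] = table.groupby("session_id")["outcome"].shift(1)
    return table
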