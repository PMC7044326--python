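"""Generative gated-accumulator model of history-dependent choices.

The agent carries three latent variables across trials:

* ``z_L`` — lateral evidence, a leaky accumulation of past responses
  with outcome-dependent update Δ_L^o and leak λ_L^o.  Its choice
  contribution is the lateral bias γ^L = z_L.
* ``z_T`` — transition evidence, a leaky accumulation of past
  repetitions/alternations T_t = r_{t−1}·r_t with updates Δ_T^{o,q}
  indexed by the outcomes of the two trials forming the transition, and
  outcome-dependent leak λ_T^o.
* ``c_T`` — a gating signal in [0, 1], updated additively by Δ_C^o after
  each outcome and clipped to its bounds.  Δ_C^− = −1 extinguishes the
  gate after a single error; Δ_C^+ = +1 restores it fully after a
  correct response.

The transition evidence only influences choice through the gated,
projected transition bias γ^T = c_T · z_T · r_{t−1}.  The probability
of a rightward response is

    p = π_R + (1 − π_R − π_L) Φ(w_stim · x_t + γ^L + γ^T + B)

with x_t the summed frame evidence, B a fixed side bias and π_R, π_L
lapse rates.  With full gate extinction after errors the model
implements the "gating" hypothesis: the bias γ^T resets after an error
while the evidence z_T is maintained and resumes driving choices after
the next correct response.  Setting instead λ_T^− = 1 with a frozen
gate (Δ_C ≡ 0, c_T ≡ 1) yields the rival "complete reset" dynamics in
which the evidence itself is erased by errors.

Because the latents are deterministic given parameters and history, the
sequential likelihood is exact and the model is fitted by penalized
maximum a posteriori over bounded parameters (no filtering needed).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr

from ._recursion import PARAM_NAMES, decision_variable, latent_traces
from .session import frame_columns

__all__ = [
    "DynamicParams",
    "LatentState",
    "LatentTrace",
    "update_latents",
    "choice_probability",
    "simulate_agent",
    "session_arrays",
    "log_likelihood",
    "fit_dynamic_model",
    "DynamicFit",
    "decompose_repeating_bias",
    "recover_parameters",
]

_UNBOUNDED = ("delta_L_plus", "delta_L_minus", "delta_T_pp", "delta_T_pm",
              "delta_T_mp", "delta_T_mm", "w_stim", "fixed_bias")

_BOUNDS = {
    "delta_L_plus": (-5.0, 5.0),
    "delta_L_minus": (-5.0, 5.0),
    "lambda_L_plus": (0.0, 1.0),
    "lambda_L_minus": (0.0, 1.0),
    "delta_T_pp": (-5.0, 5.0),
    "delta_T_pm": (-5.0, 5.0),
    "delta_T_mp": (-5.0, 5.0),
    "delta_T_mm": (-5.0, 5.0),
    "lambda_T_plus": (0.0, 1.0),
    "lambda_T_minus": (0.0, 1.0),
    "delta_C_plus": (-1.0, 1.0),
    "delta_C_minus": (-1.0, 1.0),
    "w_stim": (-5.0, 5.0),
    "fixed_bias": (-5.0, 5.0),
    "lapse_R": (0.0, 0.5),
    "lapse_L": (0.0, 0.5),
}


@dataclass(frozen=True)
class DynamicParams:
    """Parameters of the gated-accumulator agent.

    Superscripts: ``plus``/``minus`` refer to the outcome (correct /
    error) of the trial triggering the update; transition updates
    ``delta_T_oq`` are indexed by the outcomes of the earlier (o) and
    later (q) trial of the transition.  Leaks are retained-fraction
    complements: λ = 1 means full reset of the accumulator.
    """

    delta_L_plus: float = 0.03
    delta_L_minus: float = -0.03
    lambda_L_plus: float = 0.4
    lambda_L_minus: float = 0.4
    delta_T_pp: float = 0.2
    delta_T_pm: float = 0.0
    delta_T_mp: float = 0.0
    delta_T_mm: float = 0.0
    lambda_T_plus: float = 0.3
    lambda_T_minus: float = 0.3
    delta_C_plus: float = 1.0
    delta_C_minus: float = -1.0
    w_stim: float = 0.3
    fixed_bias: float = 0.0
    lapse_R: float = 0.0
    lapse_L: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lambda_L_plus", "lambda_L_minus", "lambda_T_plus", "lambda_T_minus"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("delta_C_plus", "delta_C_minus"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {v}")
        for name in ("lapse_R", "lapse_L"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5], got {v}")
        if any(not math.isfinite(getattr(self, n)) for n in PARAM_NAMES):
            raise ValueError("parameters must be finite")

    # --- canonical generative variants -------------------------------
    @classmethod
    def gating_defaults(cls) -> "DynamicParams":
        """Reference gating agent (gate extinguished by errors)."""
        return cls()

    @classmethod
    def complete_reset_defaults(cls) -> "DynamicParams":
        """Rival dynamics: errors erase z_T itself; gate frozen at 1."""
        return cls(lambda_T_minus=1.0, delta_C_plus=0.0, delta_C_minus=0.0)

    @classmethod
    def stimulus_only(cls) -> "DynamicParams":
        """History-free probit responder (all history terms zero)."""
        return cls(delta_L_plus=0.0, delta_L_minus=0.0, delta_T_pp=0.0,
                   delta_C_plus=0.0, delta_C_minus=0.0)

    # --- serialization ------------------------------------------------
    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, theta: Sequence[float]) -> "DynamicParams":
        return cls(**{n: float(v) for n, v in zip(PARAM_NAMES, theta)})

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "DynamicParams":
        return cls(**{n: float(d[n]) for n in PARAM_NAMES})

    def replace(self, **kwargs) -> "DynamicParams":
        return dataclasses.replace(self, **kwargs)


class LatentState(NamedTuple):
    """Latent state at the decision time of one trial."""

    z_L: float
    z_T: float
    c_T: float


@dataclass
class LatentTrace:
    """Per-trial latent trajectories (pre-choice states)."""

    z_L: np.ndarray
    z_T: np.ndarray
    c_T: np.ndarray
    gamma_L: np.ndarray
    gamma_T: np.ndarray
    p_right: np.ndarray


def update_latents(
    state: LatentState,
    response: int,
    outcome: str,
    prev_outcome: str | None,
    transition: int | None,
    params: DynamicParams,
) -> LatentState:
    """One-step latent update after observing a trial.

    ``transition`` is r_{t−1}·r_t (+1 repetition, −1 alternation) or
    None on a session's first trial, in which case the transition update
    is skipped.  Reference implementation of the recursion in
    :mod:`histgate._recursion`; the two must agree exactly.
    """
    if response not in (-1, 1):
        raise ValueError("response must be -1 or +1")
    if outcome not in ("correct", "error"):
        raise ValueError("outcome must be 'correct' or 'error'")
    correct = outcome == "correct"
    dl = params.delta_L_plus if correct else params.delta_L_minus
    ll = params.lambda_L_plus if correct else params.lambda_L_minus
    z_L = (1.0 - ll) * state.z_L + dl * response
    z_T = state.z_T
    if transition is not None:
        if prev_outcome not in ("correct", "error"):
            raise ValueError("prev_outcome required when a transition exists")
        lt = params.lambda_T_plus if correct else params.lambda_T_minus
        if prev_outcome == "correct":
            dt = params.delta_T_pp if correct else params.delta_T_pm
        else:
            dt = params.delta_T_mp if correct else params.delta_T_mm
        z_T = (1.0 - lt) * z_T + dt * transition
    dc = params.delta_C_plus if correct else params.delta_C_minus
    c_T = min(1.0, max(0.0, state.c_T + dc))
    return LatentState(z_L, z_T, c_T)


def choice_probability(
    state: LatentState,
    stim_evidence: float,
    prev_response: int,
    params: DynamicParams,
) -> float:
    """Probability of a rightward response given the latent state.

    ``stim_evidence`` is the summed frame evidence of the current trial;
    ``prev_response`` projects z_T into choice space (pass 0 on a
    session's first trial, where no transition bias exists).
    """
    gamma_T = state.c_T * state.z_T * prev_response
    y = params.w_stim * stim_evidence + state.z_L + gamma_T + params.fixed_bias
    phi = 0.5 * (1.0 + math.erf(y / math.sqrt(2.0)))
    return params.lapse_R + (1.0 - params.lapse_R - params.lapse_L) * phi


def _session_start_mask(table: pd.DataFrame) -> np.ndarray:
    sid = table["session_id"].to_numpy()
    start = np.empty(len(table), dtype=bool)
    start[0] = True
    start[1:] = sid[1:] != sid[:-1]
    return start


def session_arrays(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Extract the numeric arrays the recursion core consumes."""
    if len(table) == 0:
        raise ValueError("empty session table")
    fcols = frame_columns(table)
    stim = table[fcols].to_numpy(dtype=float).sum(axis=1)
    out = {
        "stim": stim,
        "session_start": _session_start_mask(table),
        "category": table["category"].to_numpy(dtype=np.int8),
    }
    if "response" in table.columns:
        resp = table["response"].to_numpy(dtype=float)
        if np.isnan(resp).any():
            raise ValueError("session contains invalid trials; filter them before fitting")
        out["responses"] = resp.astype(np.int8)
        out["outcomes"] = (out["responses"] == out["category"]).astype(np.uint8)
    return out


def simulate_agent(
    stimuli: pd.DataFrame,
    params: DynamicParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the agent on a stimulus session.

    Choices are sampled from :func:`choice_probability`; the outcome is
    correct iff the response matches the stimulus category.  Latents
    restart (z_L = z_T = 0, c_T = 1) at each session boundary.  Returns
    a copy of the table with ``response``/``outcome`` plus the latent
    trace columns ``z_L``, ``z_T``, ``c_T``, ``gamma_L``, ``gamma_T``
    and ``p_right``.
    """
    arrays = session_arrays(stimuli.drop(columns=["response", "outcome"], errors="ignore"))
    stim = arrays["stim"]
    start = arrays["session_start"]
    category = arrays["category"]
    n = len(stim)
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    responses = np.empty(n, dtype=np.int8)
    outcomes = np.empty(n, dtype=np.uint8)
    z_L = np.empty(n)
    z_T = np.empty(n)
    c_T = np.empty(n)
    gamma_T = np.empty(n)
    p_right = np.empty(n)
    state = LatentState(0.0, 0.0, 1.0)
    prev_resp = 0
    prev_out: str | None = None
    for i in range(n):
        if start[i]:
            state = LatentState(0.0, 0.0, 1.0)
            prev_resp = 0
            prev_out = None
        z_L[i], z_T[i], c_T[i] = state
        gamma_T[i] = state.c_T * state.z_T * prev_resp
        p = choice_probability(state, stim[i], prev_resp, params)
        p_right[i] = p
        r = 1 if u[i] < p else -1
        responses[i] = r
        correct = r == category[i]
        outcomes[i] = 1 if correct else 0
        outcome = "correct" if correct else "error"
        transition = None if prev_out is None else prev_resp * r
        state = update_latents(state, r, outcome, prev_out, transition, params)
        prev_resp = r
        prev_out = outcome
    table = stimuli.copy()
    table["response"] = responses.astype(int)
    table["outcome"] = np.where(outcomes == 1, "correct", "error")
    table["z_L"] = z_L
    table["z_T"] = z_T
    table["c_T"] = c_T
    table["gamma_L"] = z_L
    table["gamma_T"] = gamma_T
    table["p_right"] = p_right
    table["prev_response"] = table.groupby("session_id", sort=False)["response"].shift(1)
    table["prev_outcome"] = table.groupby("session_id", sort=False)["outcome"].shift(1)
    return table


def compute_trace(table: pd.DataFrame, params: DynamicParams) -> LatentTrace:
    """Deterministic latent trace for an observed session."""
    arrays = session_arrays(table)
    theta = params.to_vector()
    z_L, z_T, c_T, gamma_T = latent_traces(
        arrays["responses"], arrays["outcomes"], arrays["session_start"], theta
    )
    y = decision_variable(
        arrays["responses"], arrays["session_start"], arrays["stim"], z_L, z_T, c_T, theta
    )
    p = params.lapse_R + (1.0 - params.lapse_R - params.lapse_L) * ndtr(y)
    return LatentTrace(z_L=z_L, z_T=z_T, c_T=c_T, gamma_L=z_L, gamma_T=gamma_T, p_right=p)


def log_likelihood(table: pd.DataFrame, params: DynamicParams) -> float:
    """Exact sequential log-likelihood of the observed responses."""
    arrays = session_arrays(table)
    return _loglik_arrays(arrays, params.to_vector())


def _loglik_arrays(arrays: dict[str, np.ndarray], theta: np.ndarray) -> float:
    z_L, z_T, c_T, _ = latent_traces(
        arrays["responses"], arrays["outcomes"], arrays["session_start"], theta
    )
    y = decision_variable(
        arrays["responses"], arrays["session_start"], arrays["stim"], z_L, z_T, c_T, theta
    )
    lapse_r, lapse_l = theta[14], theta[15]
    p = lapse_r + (1.0 - lapse_r - lapse_l) * ndtr(y)
    pr = np.where(arrays["responses"] == 1, p, 1.0 - p)
    return float(np.log(np.clip(pr, 1e-12, None)).sum())


@dataclass
class DynamicFit:
    """Result of a MAP fit of the gated-accumulator model."""

    params: DynamicParams
    log_posterior: float
    log_likelihood: float
    converged: bool
    n_starts: int
    message: str
    start_values: np.ndarray  # best log-posterior reached from each start


def fit_dynamic_model(
    session: pd.DataFrame,
    init: DynamicParams | None = None,
    n_starts: int = 10,
    seed: int = 0,
    prior_sd: float = 10.0,
    tol: float = 1e-6,
) -> DynamicFit:
    """Fit the agent's parameters to observed choices by MAP.

    The posterior combines the exact sequential likelihood with weak
    Gaussian priors (sd ``prior_sd``) on unbounded parameters and
    uniform priors on bounded ones; optimization is bound-constrained
    L-BFGS-B from ``n_starts`` starting points (the supplied/default
    init plus random restarts).  Non-convergence of the best start is
    reported via ``converged``/``message``, returning the best iterate.
    """
    arrays = session_arrays(session)
    if len(arrays["stim"]) < 2:
        raise ValueError("need at least two trials to fit")
    prior_idx = [PARAM_NAMES.index(n) for n in _UNBOUNDED]
    bounds = [_BOUNDS[n] for n in PARAM_NAMES]

    def neg_log_post(theta: np.ndarray) -> float:
        ll = _loglik_arrays(arrays, theta)
        penalty = 0.5 * np.sum(theta[prior_idx] ** 2) / prior_sd**2
        return -(ll - penalty)

    rng = np.random.default_rng(seed)
    starts = []
    base = (init or DynamicParams.from_vector(np.zeros(16)).replace(
        lambda_L_plus=0.5, lambda_L_minus=0.5, lambda_T_plus=0.5, lambda_T_minus=0.5,
        w_stim=0.1, lapse_R=0.01, lapse_L=0.01)).to_vector()
    starts.append(base)
    for _ in range(max(0, n_starts - 1)):
        theta0 = np.empty(16)
        for j, name in enumerate(PARAM_NAMES):
            lo, hi = _BOUNDS[name]
            if name in _UNBOUNDED:
                theta0[j] = np.clip(rng.normal(0.0, 0.3), lo, hi)
            elif name.startswith("lapse"):
                theta0[j] = rng.uniform(0.001, 0.1)
            else:
                theta0[j] = rng.uniform(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo))
        theta0[PARAM_NAMES.index("w_stim")] = rng.uniform(0.0, 1.0)
        starts.append(theta0)

    best = None
    start_values = np.full(len(starts), -np.inf)
    for s, theta0 in enumerate(starts):
        res = optimize.minimize(
            neg_log_post, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": tol},
        )
        start_values[s] = -res.fun
        if best is None or res.fun < best.fun:
            best = res
    theta_hat = np.asarray(best.x)
    params = DynamicParams.from_vector(theta_hat)
    return DynamicFit(
        params=params,
        log_posterior=-float(best.fun),
        log_likelihood=_loglik_arrays(arrays, theta_hat),
        converged=bool(best.success),
        n_starts=len(starts),
        message=str(best.message),
        start_values=start_values,
    )


def decompose_repeating_bias(
    session: pd.DataFrame,
    pattern,
    params: DynamicParams | None = None,
) -> tuple[float, float, float]:
    """Split the repeating bias into lateral and transition parts.

    Over trials whose preceding history matches ``pattern`` (see
    :func:`histgate.psychometrics.match_history_pattern`), returns the
    mean projections onto the repeat/alternate axis,
    (mean γ^L·r_{t−1}, mean γ^T·r_{t−1}, their sum).  The session must
    carry latent columns (from :func:`simulate_agent`) or ``params``
    must be given to recompute the trace.
    """
    from .psychometrics import match_history_pattern

    table = session
    if "gamma_T" not in table.columns or "gamma_L" not in table.columns:
        if params is None:
            raise ValueError("session lacks latent columns; pass params to recompute")
        trace = compute_trace(table, params)
        table = table.copy()
        table["gamma_L"] = trace.gamma_L
        table["gamma_T"] = trace.gamma_T
    if "prev_response" not in table.columns:
        table = table.copy()
        table["prev_response"] = table.groupby("session_id", sort=False)["response"].shift(1)
    mask = match_history_pattern(table, pattern)
    mask &= table["prev_response"].notna().to_numpy()
    if not mask.any():
        raise ValueError("no trials match the requested history pattern")
    prev = table.loc[mask, "prev_response"].to_numpy(dtype=float)
    lateral = float((table.loc[mask, "gamma_L"].to_numpy() * prev).mean())
    transition = float((table.loc[mask, "gamma_T"].to_numpy() * prev).mean())
    return lateral, transition, lateral + transition


def recover_parameters(
    true_params: DynamicParams | None = None,
    n_sessions: int = 20,
    trials_per_session: int = 500,
    seed: int = 0,
    n_starts: int = 10,
    task_config=None,
) -> pd.DataFrame:
    """End-to-end parameter-recovery harness.

    Simulates sessions from known parameters, refits the model and
    tabulates truth vs. estimate per parameter.
    """
    from .task import TaskConfig, generate_stimulus_session

    params = true_params or DynamicParams.gating_defaults()
    config = task_config or TaskConfig()
    rng = np.random.default_rng(seed)
    pieces = []
    for s in range(n_sessions):
        stim = generate_stimulus_session(
            config, trials_per_session, seed=int(rng.integers(2**31)), session_id=f"sim{s:03d}"
        )
        pieces.append(simulate_agent(stim, params, seed=int(rng.integers(2**31))))
    data = pd.concat(pieces, ignore_index=True)
    fit = fit_dynamic_model(data, n_starts=n_starts, seed=int(rng.integers(2**31)))
    truth = params.to_dict()
    est = fit.params.to_dict()
    return pd.DataFrame(
        {
            "parameter": list(PARAM_NAMES),
            "truth": [truth[n] for n in PARAM_NAMES],
            "estimate": [est[n] for n in PARAM_NAMES],
            "abs_error": [abs(est[n] - truth[n]) for n in PARAM_NAMES],
        }
    )
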