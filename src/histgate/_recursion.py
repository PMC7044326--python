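"""Sequential latent-variable recursion (JIT-compiled inner loop).

The generative agent's latents are deterministic functions of the
parameters and the observed trial history, so fitting needs many fast
re-evaluations of the same recursion; this module holds the tight loop,
compiled with numba.  Parameter vectors are laid out per ``PARAM_NAMES``.

Update rules applied after each trial t (response r_t ∈ {−1,+1},
outcome o_t ∈ {+,−}, transition T_t = r_{t−1}·r_t):

    z_L ← (1 − λ_L^{o_t}) z_L + Δ_L^{o_t} · r_t
    z_T ← (1 − λ_T^{o_t}) z_T + Δ_T^{o_{t−1}, o_t} · T_t   (skipped on
          the first trial of a session, which has no transition)
    c_T ← clip(c_T + Δ_C^{o_t}, 0, 1)

and the pre-choice decision variable of trial t is

    y_t = w_stim · x_t + z_L + c_T · z_T · r_{t−1} + fixed_bias

with x_t the summed frame evidence.  Latents start each session at
z_L = z_T = 0, c_T = 1.
"""

from __future__ import annotations

import numpy as np
from numba import njit

PARAM_NAMES = (
    "delta_L_plus",
    "delta_L_minus",
    "lambda_L_plus",
    "lambda_L_minus",
    "delta_T_pp",
    "delta_T_pm",
    "delta_T_mp",
    "delta_T_mm",
    "lambda_T_plus",
    "lambda_T_minus",
    "delta_C_plus",
    "delta_C_minus",
    "w_stim",
    "fixed_bias",
    "lapse_R",
    "lapse_L",
)

# indices used by the jitted code
_DLP, _DLM, _LLP, _LLM = 0, 1, 2, 3
_DTPP, _DTPM, _DTMP, _DTMM = 4, 5, 6, 7
_LTP, _LTM, _DCP, _DCM = 8, 9, 10, 11
_WSTIM, _BIAS, _LAPSE_R, _LAPSE_L = 12, 13, 14, 15


@njit(cache=False)
def latent_traces(responses, outcomes, session_start, theta):
    """Pre-choice latent trajectories for an observed response sequence.

    Parameters
    ----------
    responses : int8 array, values −1/+1
    outcomes : uint8 array, 1 correct / 0 error
    session_start : bool array, True on each session's first trial
    theta : float64 array laid out per PARAM_NAMES

    Returns
    -------
    z_L, z_T, c_T, gamma_T : float64 arrays (state at decision time;
    gamma_T = c_T · z_T · r_{t−1}, zero on session-initial trials).
    """
    n = responses.shape[0]
    z_L = np.empty(n)
    z_T = np.empty(n)
    c_T = np.empty(n)
    gamma_T = np.empty(n)
    zl = 0.0
    zt = 0.0
    ct = 1.0
    for i in range(n):
        if session_start[i]:
            zl = 0.0
            zt = 0.0
            ct = 1.0
        z_L[i] = zl
        z_T[i] = zt
        c_T[i] = ct
        if session_start[i]:
            gamma_T[i] = 0.0
        else:
            gamma_T[i] = ct * zt * responses[i - 1]
        r = responses[i]
        if outcomes[i] == 1:
            dl, ll = theta[_DLP], theta[_LLP]
            lt, dc = theta[_LTP], theta[_DCP]
        else:
            dl, ll = theta[_DLM], theta[_LLM]
            lt, dc = theta[_LTM], theta[_DCM]
        zl = (1.0 - ll) * zl + dl * r
        if not session_start[i]:
            trans = responses[i - 1] * r
            if outcomes[i - 1] == 1:
                dt = theta[_DTPP] if outcomes[i] == 1 else theta[_DTPM]
            else:
                dt = theta[_DTMP] if outcomes[i] == 1 else theta[_DTMM]
            zt = (1.0 - lt) * zt + dt * trans
        ct = ct + dc
        if ct > 1.0:
            ct = 1.0
        elif ct < 0.0:
            ct = 0.0
    return z_L, z_T, c_T, gamma_T


@njit(cache=False)
def decision_variable(responses, session_start, stim, z_L, z_T, c_T, theta):
    """Probit argument y_t per trial from precomputed latent traces."""
    n = responses.shape[0]
    y = np.empty(n)
    for i in range(n):
        g = 0.0 if session_start[i] else c_T[i] * z_T[i] * responses[i - 1]
        y[i] = theta[_WSTIM] * stim[i] + z_L[i] + g + theta[_BIAS]
    return y
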