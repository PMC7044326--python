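"""Lag-k transfer of the transition bias, conditioned on outcomes.

The transfer coefficient γ^T_t → γ^T_{t+k} measures how predictive the
transition bias at trial t is of the choice k trials later, separately
for each sequence of intervening outcomes.  It discriminates two
hypotheses about what errors do to the internal transition estimate:

* complete reset — an error erases the accumulated transition evidence
  z^T, so the bias before an error carries no information about choices
  after it (the lag-2 coefficient conditioned on (error, correct) is
  zero);
* gating — an error only blocks the conversion of z^T into a bias, so
  after the next correct response the old bias resumes driving choices
  (the (error, correct) lag-2 coefficient rebounds to near its
  no-error value).

The coefficient is a probit regression of the choice at t+k, coded on
the repeat axis relative to r_{t+k−1}, on the repeat-axis transition
bias at t (γ^T_t·r_{t−1} = c^T_t·z^T_t), with the trial-(t+k) repeating
stimulus evidence as covariate, over trials whose outcomes at
t..t+k−1 match the requested pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .agent import DynamicParams, compute_trace
from .glm import DesignMatrix, GLMWeights, build_design_matrix

__all__ = ["TransferResult", "infer_gamma_series", "transfer_coefficient", "transfer_curve"]


@dataclass
class TransferResult:
    """Outcome-conditioned lag-k transfer coefficient."""

    lag: int
    outcome_pattern: tuple
    coefficient: float
    se: float
    n_trials: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")


def infer_gamma_series(session: pd.DataFrame, model) -> np.ndarray:
    """Per-trial transition bias γ^T implied by a fitted model.

    ``model`` is either :class:`DynamicParams` (the latent recursion is
    replayed on the observed history) or a fitted :class:`GLMWeights`
    (γ^T is the transition-kernel part of the decision variable).
    """
    if isinstance(model, DynamicParams):
        return compute_trace(session, model).gamma_T
    if isinstance(model, GLMWeights):
        design = build_design_matrix(session)
        w = np.nan_to_num(model.weights, nan=0.0)
        trans = np.array([c.family == "transition" for c in design.columns])
        return design.X[:, trans] @ w[trans]
    raise ValueError("model must be DynamicParams or GLMWeights")


def _parse_outcome_pattern(outcome_pattern) -> tuple:
    if isinstance(outcome_pattern, str):
        outcome_pattern = outcome_pattern.replace(",", " ").split()
    pattern = tuple(outcome_pattern)
    for o in pattern:
        if o not in ("correct", "error"):
            raise ValueError(f"outcome pattern entries must be 'correct'/'error', got {o!r}")
    return pattern


def transfer_coefficient(
    session: pd.DataFrame,
    gamma: np.ndarray,
    k: int,
    outcome_pattern,
    include_stimulus: bool = True,
    n_boot: int = 0,
    seed: int = 0,
) -> TransferResult:
    """Transfer coefficient at lag ``k`` for one outcome pattern.

    ``outcome_pattern`` lists the outcomes of trials t..t+k−1 (length
    k).  ``gamma`` is the per-trial γ^T series aligned with ``session``
    (see :func:`infer_gamma_series`).  Standard errors are Wald by
    default; with ``n_boot`` > 0 a bootstrap (over sessions when several
    are present, else over trials) yields a percentile 95% CI.
    """
    pattern = _parse_outcome_pattern(outcome_pattern)
    if k < 1:
        raise ValueError("lag k must be >= 1")
    if len(pattern) != k:
        raise ValueError(f"outcome pattern must have length k={k}")
    gamma = np.asarray(gamma, dtype=float)
    n = len(session)
    if gamma.shape[0] != n:
        raise ValueError("gamma series length must match session length")

    resp = session["response"].to_numpy(dtype=float)
    outc = (session["outcome"].astype(str) == "correct").to_numpy()
    sid = session["session_id"].to_numpy()
    ev = session["evidence"].to_numpy(dtype=float)
    pos = session.groupby("session_id", sort=False).cumcount().to_numpy()

    base = np.zeros(n, dtype=bool)
    limit = n - k
    idx = np.arange(limit)
    ok = pos[idx] >= 1  # γ^T_t needs a previous response
    ok &= sid[idx] == sid[idx + k]  # window within one session
    for j, o in enumerate(pattern):
        ok &= outc[idx + j] == (o == "correct")
    for j in range(k + 1):
        ok &= ~np.isnan(resp[idx + j])
    base[idx[ok]] = True
    t = np.flatnonzero(base)
    if t.size == 0:
        raise ValueError("no trials match the requested outcome pattern")

    y = (resp[t + k] == resp[t + k - 1]).astype(float)
    x_bias = gamma[t] * resp[t - 1]  # repeat-axis bias c^T·z^T at t
    sess = sid[t]
    cols = [x_bias]
    if include_stimulus:
        cols.append(ev[t + k] * resp[t + k - 1])
    X = np.column_stack(cols + [np.ones_like(x_bias)])

    def _coef(Xm, ym):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Probit(ym, Xm).fit(disp=0, maxiter=200)
        return res

    res = _coef(X, y)
    coef = float(res.params[0])
    se = float(res.bse[0])
    out = TransferResult(
        lag=k, outcome_pattern=pattern, coefficient=coef, se=se, n_trials=int(t.size)
    )
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        uniq = np.unique(sess)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            if uniq.size > 1:
                pick = rng.choice(uniq, size=uniq.size, replace=True)
                rows = np.concatenate([np.flatnonzero(sess == s) for s in pick])
            else:
                rows = rng.integers(0, t.size, size=t.size)
            try:
                boot[b] = float(_coef(X[rows], y[rows]).params[0])
            except Exception:
                boot[b] = np.nan
        ok_b = ~np.isnan(boot)
        out.ci_low, out.ci_high = (
            float(np.percentile(boot[ok_b], 2.5)),
            float(np.percentile(boot[ok_b], 97.5)),
        )
    return out


def transfer_curve(
    session: pd.DataFrame,
    gamma: np.ndarray,
    max_lag: int = 4,
    include_stimulus: bool = True,
) -> pd.DataFrame:
    """Tidy table of transfer coefficients versus lag.

    For each lag k up to ``max_lag``, evaluates the three outcome
    families of the analysis: all intervening trials correct, an error
    at t followed by corrects (reset-and-rebound probe), and all
    intervening trials incorrect.
    """
    rows = []
    for k in range(1, max_lag + 1):
        families = {
            "all_correct": ("correct",) * k,
            "error_then_correct": ("error",) + ("correct",) * (k - 1),
            "all_error": ("error",) * k,
        }
        for name, pattern in families.items():
            try:
                r = transfer_coefficient(
                    session, gamma, k, pattern, include_stimulus=include_stimulus
                )
            except ValueError:
                continue
            rows.append(
                {
                    "lag": k,
                    "family": name,
                    "pattern": " ".join(pattern),
                    "coefficient": r.coefficient,
                    "se": r.se,
                    "n_trials": r.n_trials,
                }
            )
    return pd.DataFrame(rows)
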