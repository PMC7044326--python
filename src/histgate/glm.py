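"""Trial-history GLM with probit link and lapse rates.

The probability of a rightward response is modeled as

    p(r_t = +1) = π_R + (1 − π_L − π_R) Φ(y_t)

with decision variable

    y_t = Σ_f ω^S_f S_{t,f} + Σ_k ω^A_k S^sum_{t−k}
        + Σ_{o,k} ω^L_{k,o} r^o_{t−k}
        + ( Σ_{o,q,k} ω^T_{k,o,q} T^{o,q}_{t−k} ) · r_{t−1} + β

where S_{t,f} are the current trial's frame evidences, S^sum the summed
frame evidence of past trials (a slow sensory after-effect), r^+/r^−
past correct/error responses coded −1/0/+1, and
T^{o,q}_{t−k} = r^o_{t−k−1} · r^q_{t−k} past transitions (+1 repetition,
−1 alternation, 0 if the outcome pair does not match o,q), projected
into choice space by the previous response r_{t−1}.  History covers ten
trials back, with lags 6–10 pooled into a single weight per family.

Fits are penalized MLE (small L2 ridge) over weights plus the two lapse
rates, optionally restricted to trials following a correct or an error
response — the split that exposes the outcome gating of the transition
kernels.  Conditioning makes some low-lag regressors exactly collinear;
these are detected by a rank check and dropped deterministically,
preferring to keep transition columns (the kernels of interest).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr
from scipy.stats import norm

from .session import frame_columns

__all__ = [
    "ColumnInfo",
    "DesignMatrix",
    "GLMWeights",
    "build_design_matrix",
    "fit_glm",
    "predict_glm",
    "compare_models",
]

TRANSITION_TYPES = ("pp", "pm", "mp", "mm")
# rank-pruning keep priority (lower = kept first)
_FAMILY_PRIORITY = {"intercept": 0, "stimulus": 1, "transition": 2, "lateral": 3, "after_effect": 4}


class ColumnInfo(NamedTuple):
    family: str
    subtype: str
    lag: int

    @property
    def name(self) -> str:
        if self.family == "intercept":
            return "intercept"
        if self.family == "stimulus":
            return f"stim_{self.subtype}"
        if self.family == "after_effect":
            return f"aftereffect_lag{self.lag}"
        return f"{self.family}_{self.subtype}_lag{self.lag}"


@dataclass
class DesignMatrix:
    """Regressor matrix plus per-trial metadata for the history GLM."""

    X: np.ndarray
    columns: list[ColumnInfo]
    response: np.ndarray          # +1/-1 (NaN invalid)
    prev_outcome: np.ndarray      # 1 correct / 0 error / NaN undefined
    fit_mask: np.ndarray          # rows eligible for fitting
    session_id: np.ndarray
    n_lags: int
    pooled_tail_to: int

    def column_index(self, name: str) -> int:
        for i, c in enumerate(self.columns):
            if c.name == name:
                return i
        raise KeyError(name)

    def rows(self, condition: str = "all") -> np.ndarray:
        """Row mask for a previous-outcome condition."""
        if condition == "all":
            return self.fit_mask
        if condition == "after_correct":
            return self.fit_mask & (self.prev_outcome == 1)
        if condition == "after_error":
            return self.fit_mask & (self.prev_outcome == 0)
        raise ValueError(f"unknown condition {condition!r}")


def _lagged(x: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros_like(x)
    if k < len(x):
        out[k:] = x[:-k] if k > 0 else x
    return out


def build_design_matrix(
    session: pd.DataFrame, n_lags: int = 6, pooled_tail_to: int = 10
) -> DesignMatrix:
    """Construct the lagged history regressors from a session table.

    Lags 1..n_lags−1 enter individually; the final lag pools
    n_lags..pooled_tail_to into one regressor (the sum of the
    constituent lag regressors, sharing one weight).  History never
    crosses session boundaries (zero padding).  Invalid trials
    contribute 0 to history regressors; trials with an invalid current
    or previous response are excluded from fitting via ``fit_mask``.
    """
    fcols = frame_columns(session)
    n = len(session)
    blocks: list[np.ndarray] = []
    columns: list[ColumnInfo] = []

    frames_all = session[fcols].to_numpy(dtype=float)
    resp_all = session["response"].to_numpy(dtype=float) if "response" in session.columns else np.full(n, np.nan)
    cat_all = session["category"].to_numpy(dtype=float)
    sid = session["session_id"].to_numpy()

    columns.append(ColumnInfo("intercept", "", 0))
    for f in range(frames_all.shape[1]):
        columns.append(ColumnInfo("stimulus", f"f{f + 1}", 0))
    for k in range(1, n_lags + 1):
        columns.append(ColumnInfo("after_effect", "", k))
    for o in ("plus", "minus"):
        for k in range(1, n_lags + 1):
            columns.append(ColumnInfo("lateral", o, k))
    for oq in TRANSITION_TYPES:
        for k in range(1, n_lags + 1):
            columns.append(ColumnInfo("transition", oq, k))

    X = np.zeros((n, len(columns)))
    X[:, 0] = 1.0
    X[:, 1 : 1 + frames_all.shape[1]] = frames_all

    prev_outcome = np.full(n, np.nan)
    fit_mask = np.zeros(n, dtype=bool)

    start = 0
    for s in range(1, n + 1):
        if s == n or sid[s] != sid[start]:
            sl = slice(start, s)
            r = resp_all[sl]
            valid = ~np.isnan(r)
            correct = valid & (r == cat_all[sl])
            r0 = np.where(valid, r, 0.0)
            r_plus = np.where(correct, r0, 0.0)
            r_minus = np.where(valid & ~correct, r0, 0.0)
            s_sum = frames_all[sl].sum(axis=1)
            trans = {oq: np.zeros(s - start) for oq in TRANSITION_TYPES}
            trans["pp"][1:] = r_plus[:-1] * r_plus[1:]
            trans["pm"][1:] = r_plus[:-1] * r_minus[1:]
            trans["mp"][1:] = r_minus[:-1] * r_plus[1:]
            trans["mm"][1:] = r_minus[:-1] * r_minus[1:]
            r_prev = _lagged(r0, 1)

            col = 1 + frames_all.shape[1]
            for k in range(1, n_lags + 1):
                lags = [k] if k < n_lags else list(range(n_lags, pooled_tail_to + 1))
                X[sl, col] = sum(_lagged(s_sum, kk) for kk in lags)
                col += 1
            for series in (r_plus, r_minus):
                for k in range(1, n_lags + 1):
                    lags = [k] if k < n_lags else list(range(n_lags, pooled_tail_to + 1))
                    X[sl, col] = sum(_lagged(series, kk) for kk in lags)
                    col += 1
            for oq in TRANSITION_TYPES:
                for k in range(1, n_lags + 1):
                    lags = [k] if k < n_lags else list(range(n_lags, pooled_tail_to + 1))
                    X[sl, col] = sum(_lagged(trans[oq], kk) for kk in lags) * r_prev
                    col += 1

            po = np.full(s - start, np.nan)
            po[1:] = np.where(valid[:-1], correct[:-1].astype(float), np.nan)
            prev_outcome[sl] = po
            fm = valid.copy()
            fm[0] = False  # session-initial: no previous outcome
            fm[1:] &= valid[:-1]
            fit_mask[sl] = fm
            start = s

    return DesignMatrix(
        X=X,
        columns=columns,
        response=resp_all,
        prev_outcome=prev_outcome,
        fit_mask=fit_mask,
        session_id=sid,
        n_lags=n_lags,
        pooled_tail_to=pooled_tail_to,
    )


@dataclass
class GLMWeights:
    """Fitted history-GLM weights with lapses and diagnostics."""

    columns: list[ColumnInfo]
    weights: np.ndarray           # NaN for dropped columns
    se: np.ndarray
    lapse_R: float
    lapse_L: float
    condition: str
    loglik: float
    n_trials: int
    n_params: int
    converged: bool
    dropped: list[str] = field(default_factory=list)
    l2: float = 1e-4

    def weight(self, name: str) -> float:
        for c, w in zip(self.columns, self.weights):
            if c.name == name:
                return float(w)
        raise KeyError(name)

    def kernel(self, family: str, subtype: str = "") -> pd.DataFrame:
        """Lag-resolved kernel of one regressor family as a tidy table."""
        rows = [
            {"lag": c.lag, "weight": w, "se": s}
            for c, w, s in zip(self.columns, self.weights, self.se)
            if c.family == family and (not subtype or c.subtype == subtype)
        ]
        return pd.DataFrame(rows).sort_values("lag").reset_index(drop=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "family": [c.family for c in self.columns],
                "subtype": [c.subtype for c in self.columns],
                "lag": [c.lag for c in self.columns],
                "weight": self.weights,
                "se": self.se,
            }
        )


def _prune_collinear(X: np.ndarray, columns: list[ColumnInfo], tol: float = 1e-8):
    """Greedy rank selection keeping columns in family-priority order.

    Returns indices of kept columns (in original order) and names of
    dropped ones.  Intercept and stimulus are considered first, then
    transition, lateral, after-effect — so indeterminacies between
    transition and lateral regressors at low lags resolve in favor of
    the transition kernel.
    """
    order = sorted(
        range(len(columns)), key=lambda i: (_FAMILY_PRIORITY[columns[i].family], i)
    )
    kept: list[int] = []
    Q = np.empty((X.shape[0], 0))
    for i in order:
        c = X[:, i]
        nrm = np.linalg.norm(c)
        if nrm < tol * np.sqrt(X.shape[0]):
            continue  # (near-)zero column
        resid = c - Q @ (Q.T @ c) if Q.shape[1] else c.copy()
        # one re-orthogonalization pass for numerical safety
        if Q.shape[1]:
            resid -= Q @ (Q.T @ resid)
        rn = np.linalg.norm(resid)
        if rn > 1e-6 * nrm:
            kept.append(i)
            Q = np.column_stack([Q, resid / rn])
    kept = sorted(kept)
    dropped = [columns[i].name for i in range(len(columns)) if i not in set(kept)]
    return kept, dropped


def _nll_and_grad(params, X, v, l2):
    p_dim = X.shape[1]
    w = params[:p_dim]
    lr, ll = params[p_dim], params[p_dim + 1]
    y = X @ w
    Phi = ndtr(y)
    scale = 1.0 - lr - ll
    p = np.clip(lr + scale * Phi, 1e-10, 1.0 - 1e-10)
    u = v / p - (1.0 - v) / (1.0 - p)
    phi = norm.pdf(y)
    nll = -(v * np.log(p) + (1.0 - v) * np.log(1.0 - p)).sum() + 0.5 * l2 * (w @ w)
    g_w = -(X.T @ (u * scale * phi)) + l2 * w
    g_lr = -np.sum(u * (1.0 - Phi))
    g_ll = -np.sum(u * (-Phi))
    return nll, np.concatenate([g_w, [g_lr, g_ll]])


def fit_glm(
    design: DesignMatrix,
    condition: str = "all",
    l2: float = 1e-4,
    compute_se: bool = True,
    maxiter: int = 500,
) -> GLMWeights:
    """Penalized-MLE fit of the history GLM on one outcome condition.

    ``condition`` restricts the fit to all trials, trials after a
    correct response, or trials after an error.  Lapses are bounded in
    [0, 0.5]; weights carry a small L2 penalty.  Standard errors come
    from the observed information of the weight block at the optimum.
    """
    rows = design.rows(condition)
    if rows.sum() < 10:
        raise ValueError(f"too few trials ({int(rows.sum())}) in condition {condition!r}")
    Xc = design.X[rows]
    v = (design.response[rows] == 1).astype(float)
    if np.unique(v).size < 2:
        raise ValueError("responses are one-sided; cannot fit (complete separation)")
    kept, dropped = _prune_collinear(Xc, design.columns)
    Xk = Xc[:, kept]
    p_dim = Xk.shape[1]
    x0 = np.concatenate([np.zeros(p_dim), [0.02, 0.02]])
    bounds = [(None, None)] * p_dim + [(1e-8, 0.5), (1e-8, 0.5)]
    res = optimize.minimize(
        _nll_and_grad,
        x0,
        args=(Xk, v, l2),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-10},
    )
    w_hat = res.x[:p_dim]
    lr, ll_ = res.x[p_dim], res.x[p_dim + 1]

    weights = np.full(len(design.columns), np.nan)
    se = np.full(len(design.columns), np.nan)
    weights[kept] = w_hat
    if compute_se:
        y = Xk @ w_hat
        Phi = ndtr(y)
        scale = 1.0 - lr - ll_
        p = np.clip(lr + scale * Phi, 1e-10, 1.0 - 1e-10)
        u = v / p - (1.0 - v) / (1.0 - p)
        du_dp = -v / p**2 - (1.0 - v) / (1.0 - p) ** 2
        phi = norm.pdf(y)
        dc_dy = scale * (du_dp * scale * phi**2 - u * y * phi)
        H = Xk.T @ (Xk * (-dc_dy)[:, None]) + l2 * np.eye(p_dim)
        try:
            cov = np.linalg.inv(H)
            se[kept] = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            pass

    nll_pen = res.fun - 0.5 * l2 * (w_hat @ w_hat)
    return GLMWeights(
        columns=list(design.columns),
        weights=weights,
        se=se,
        lapse_R=float(lr),
        lapse_L=float(ll_),
        condition=condition,
        loglik=-float(nll_pen),
        n_trials=int(rows.sum()),
        n_params=p_dim + 2,
        converged=bool(res.success),
        dropped=dropped,
        l2=l2,
    )


def predict_glm(weights: GLMWeights, design: DesignMatrix) -> np.ndarray:
    """Per-trial rightward probability under fitted weights.

    Dropped (collinear) columns contribute zero.  Probabilities lie in
    [π_R, 1 − π_L] by construction.
    """
    if len(weights.columns) != len(design.columns) or any(
        a.name != b.name for a, b in zip(weights.columns, design.columns)
    ):
        raise ValueError("design matrix structure does not match fitted weights")
    w = np.nan_to_num(weights.weights, nan=0.0)
    y = design.X @ w
    return weights.lapse_R + (1.0 - weights.lapse_R - weights.lapse_L) * ndtr(y)


def _heldout_loglik(fits: list[GLMWeights], design: DesignMatrix) -> float:
    total = 0.0
    for fit in fits:
        rows = design.rows(fit.condition)
        p = np.clip(predict_glm(fit, design)[rows], 1e-10, 1 - 1e-10)
        v = (design.response[rows] == 1).astype(float)
        total += float((v * np.log(p) + (1 - v) * np.log(1 - p)).sum())
    return total


def compare_models(
    models: dict[str, list[GLMWeights]],
    design: DesignMatrix,
    heldout: DesignMatrix | None = None,
) -> pd.DataFrame:
    """Rank candidate GLMs by BIC (and held-out log-likelihood).

    Each model is a list of fits jointly covering the fitted trials
    (e.g. ``[fit_all]`` for a pooled model, or
    ``[fit_after_correct, fit_after_error]`` for the outcome-split
    model).  BIC uses the total parameter count and the total number of
    in-sample trials; lower is better.
    """
    rows = []
    for name, fits in models.items():
        n = sum(f.n_trials for f in fits)
        k = sum(f.n_params for f in fits)
        ll = _heldout_loglik(fits, design)
        row = {
            "model": name,
            "n_params": k,
            "n_trials": n,
            "loglik": ll,
            "bic": k * np.log(n) - 2.0 * ll,
        }
        if heldout is not None:
            row["heldout_loglik"] = _heldout_loglik(fits, heldout)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)
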