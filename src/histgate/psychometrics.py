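"""Probit psychometric curves and sequence-conditioned repeating bias.

Two curves summarize a session.  The rightward curve is the probability
of a rightward response versus signed stimulus evidence e, fitted as
P(right) = Φ(β·e + B) where B is the fixed side bias.  The repeating
curve is the probability of repeating the previous response versus the
repeating stimulus evidence ê_t = r_{t−1}·e_t, fitted as
P(repeat) = Φ(β′·ê + b) where b is the repeating bias (b > 0: tendency
to repeat).  Both are lapse-free two-parameter probits fitted by
Bernoulli maximum likelihood, with nonparametric-bootstrap uncertainty.

The repeating bias can be conditioned on the recent trial history using
a small pattern language (see :func:`parse_pattern`): e.g. the bias
after n consecutive correct repetitions, or after such a sequence
terminated by an error — the build-up / reset curves of the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PsychometricFit",
    "repeating_evidence",
    "fit_probit",
    "rightward_fit",
    "repeating_fit",
    "parse_pattern",
    "repetition_pattern",
    "alternation_pattern",
    "match_history_pattern",
    "repeating_bias_conditioned",
    "bias_buildup_curve",
]

MIN_TRIALS_PER_LEVEL = 10


@dataclass
class PsychometricFit:
    """Two-parameter probit fit P = Φ(sensitivity · x + bias)."""

    sensitivity: float
    bias: float
    n_trials: int
    level_counts: dict = field(default_factory=dict)
    sensitivity_sd: float = float("nan")
    bias_sd: float = float("nan")
    bias_quartiles: tuple = (float("nan"), float("nan"))
    stable: bool = True

    def predict(self, x: np.ndarray) -> np.ndarray:
        from scipy.special import ndtr

        return ndtr(self.sensitivity * np.asarray(x, dtype=float) + self.bias)


def repeating_evidence(evidence, prev_response):
    """Project stimulus evidence onto the repeat axis: ê = r_{t−1}·e.

    Positive ê favors repeating the previous response, negative ê favors
    alternating.  Undefined (NaN) where the previous response is missing
    (session-initial or post-invalid trials); such trials are excluded
    from repeating-curve fits.
    """
    prev = np.asarray(prev_response, dtype=float)
    if prev.ndim == 0:
        if not np.isin(prev, (-1.0, 1.0)):
            raise ValueError("prev_response must be -1 or +1")
        return float(prev) * float(evidence)
    return prev * np.asarray(evidence, dtype=float)


def _probit_mle(x: np.ndarray, y: np.ndarray, start=None) -> tuple[float, float]:
    exog = np.column_stack([x, np.ones_like(x)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Probit(y, exog).fit(disp=0, start_params=start, maxiter=200)
    beta, bias = res.params
    if not (np.isfinite(beta) and np.isfinite(bias)) or abs(beta) > 1e3 or abs(bias) > 1e3:
        raise ValueError("degenerate probit fit (separation?)")
    return float(beta), float(bias)


def fit_probit(
    x,
    y,
    n_boot: int = 0,
    seed: int = 0,
    min_per_level: int = MIN_TRIALS_PER_LEVEL,
) -> PsychometricFit:
    """Bernoulli-MLE probit fit of binary responses on evidence values.

    ``y`` is 1 for the modeled response class (rightward, or repeat),
    0 otherwise.  Requires at least two distinct evidence levels and
    both response classes; separation is reported as an error.  With
    ``n_boot`` > 0, a nonparametric bootstrap over trials yields one-sd
    uncertainties and bias quartiles.  Fits with any evidence level
    holding fewer than ``min_per_level`` trials are flagged unstable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    levels, counts = np.unique(x, return_counts=True)
    if levels.size < 2:
        raise ValueError("need at least two distinct evidence levels")
    if np.unique(y).size < 2:
        raise ValueError("need both response classes present")
    beta, bias = _probit_mle(x, y)
    fit = PsychometricFit(
        sensitivity=beta,
        bias=bias,
        n_trials=int(x.size),
        level_counts={float(lv): int(c) for lv, c in zip(levels, counts)},
        stable=bool(counts.min() >= min_per_level),
    )
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_boot, 2))
        start = np.array([beta, bias])
        for b in range(n_boot):
            idx = rng.integers(0, x.size, size=x.size)
            try:
                boot[b] = _probit_mle(x[idx], y[idx], start=start)
            except ValueError:
                boot[b] = np.nan
        ok = ~np.isnan(boot).any(axis=1)
        fit.sensitivity_sd = float(np.std(boot[ok, 0], ddof=1))
        fit.bias_sd = float(np.std(boot[ok, 1], ddof=1))
        q1, q3 = np.percentile(boot[ok, 1], [25, 75])
        fit.bias_quartiles = (float(q1), float(q3))
    return fit


def rightward_fit(session: pd.DataFrame, **kwargs) -> PsychometricFit:
    """Rightward psychometric: P(right) = Φ(β·e + B)."""
    mask = session["response"].notna()
    e = session.loc[mask, "evidence"].to_numpy(dtype=float)
    right = (session.loc[mask, "response"].to_numpy(dtype=float) == 1).astype(float)
    return fit_probit(e, right, **kwargs)


def repeating_fit(session: pd.DataFrame, **kwargs) -> PsychometricFit:
    """Repeating psychometric: P(repeat) = Φ(β′·ê + b)."""
    mask = session["response"].notna() & session["prev_response"].notna()
    e = session.loc[mask, "evidence"].to_numpy(dtype=float)
    prev = session.loc[mask, "prev_response"].to_numpy(dtype=float)
    rep = (session.loc[mask, "response"].to_numpy(dtype=float) == prev).astype(float)
    return fit_probit(repeating_evidence(e, prev), rep, **kwargs)


# ----------------------------------------------------------------------
# history-pattern language
#
# A pattern is a sequence of per-trial tokens anchored to end at trial
# t−1.  Each token constrains one trial: its outcome and/or the
# transition (repetition or alternation) that led into it.  String
# form: whitespace-separated tokens over
#
#     c / +   any-transition correct trial
#     e / -   any-transition error trial
#     r+ r-   repetition into a correct / error trial
#     a+ a-   alternation into a correct / error trial
#     r  a    repetition / alternation, either outcome
#     .       any trial (no constraint)
#
# "c r+ r+" thus matches trials preceded by two correct repetitions
# among three correct responses; "c r+ r+ e" the same run terminated by
# an error at t−1.
# ----------------------------------------------------------------------

_TOKEN_MAP = {
    "c": (None, "correct"),
    "+": (None, "correct"),
    "e": (None, "error"),
    "-": (None, "error"),
    "r": ("rep", None),
    "a": ("alt", None),
    "r+": ("rep", "correct"),
    "r-": ("rep", "error"),
    "a+": ("alt", "correct"),
    "a-": ("alt", "error"),
    ".": (None, None),
}


def parse_pattern(pattern) -> list[tuple]:
    """Parse a history pattern into (transition, outcome) tokens."""
    if isinstance(pattern, str):
        tokens = pattern.lower().split()
        try:
            parsed = [_TOKEN_MAP[t] for t in tokens]
        except KeyError as exc:
            raise ValueError(f"unknown pattern token {exc.args[0]!r}") from None
    else:
        parsed = [tuple(t) for t in pattern]
        for trans, outc in parsed:
            if trans not in (None, "rep", "alt") or outc not in (None, "correct", "error"):
                raise ValueError(f"bad pattern token {(trans, outc)!r}")
    if not parsed:
        raise ValueError("empty pattern")
    return parsed


def repetition_pattern(n: int, terminated_by_error: bool = False) -> list[tuple]:
    """History of n correct repetitions (n+1 correct trials), optionally
    followed by a terminating error at trial t−1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    tokens = [(None, "correct")] + [("rep", "correct")] * n
    if terminated_by_error:
        tokens.append((None, "error"))
    return tokens


def alternation_pattern(n: int, terminated_by_error: bool = False) -> list[tuple]:
    """History of n correct alternations, optionally error-terminated."""
    if n < 1:
        raise ValueError("n must be >= 1")
    tokens = [(None, "correct")] + [("alt", "correct")] * n
    if terminated_by_error:
        tokens.append((None, "error"))
    return tokens


def match_history_pattern(session: pd.DataFrame, pattern) -> np.ndarray:
    """Boolean mask of trials t whose history t−m..t−1 matches ``pattern``.

    Token j (0-based, pattern length m) constrains trial t−m+j; all
    pattern trials must lie in the same session as t and carry valid
    responses.  Transition constraints additionally require the
    predecessor of the constrained trial to exist in-session.
    """
    tokens = parse_pattern(pattern)
    m = len(tokens)
    n = len(session)
    resp = session["response"].to_numpy(dtype=float)
    if "outcome" in session.columns:
        outc = session["outcome"].astype(str).to_numpy()
    else:
        outc = np.where(resp == session["category"].to_numpy(), "correct", "error")
    sid = session["session_id"].to_numpy()
    pos = session.groupby("session_id", sort=False).cumcount().to_numpy()

    valid = ~np.isnan(resp)
    prev_same = np.zeros(n, dtype=bool)
    prev_same[1:] = sid[1:] == sid[:-1]
    is_rep = np.zeros(n, dtype=bool)
    is_alt = np.zeros(n, dtype=bool)
    both = prev_same.copy()
    both[1:] &= valid[1:] & valid[:-1]
    is_rep[1:] = both[1:] & (resp[1:] == resp[:-1])
    is_alt[1:] = both[1:] & (resp[1:] == -resp[:-1])
    is_correct = valid & (outc == "correct")
    is_error = valid & (outc == "error")

    mask = pos >= m  # trial t needs m in-session predecessors
    for j, (trans, outcome) in enumerate(tokens):
        shift = m - j  # token j sits at t - shift
        tok = valid.copy()
        if outcome == "correct":
            tok &= is_correct
        elif outcome == "error":
            tok &= is_error
        if trans == "rep":
            tok &= is_rep
        elif trans == "alt":
            tok &= is_alt
        shifted = np.zeros(n, dtype=bool)
        shifted[shift:] = tok[:-shift]
        mask &= shifted
    return mask


def repeating_bias_conditioned(
    session: pd.DataFrame,
    pattern,
    n_boot: int = 0,
    seed: int = 0,
    **kwargs,
) -> PsychometricFit:
    """Repeating-probit fit restricted to trials matching a history pattern.

    Selects trials whose immediately preceding history matches
    ``pattern`` (see :func:`parse_pattern`) and fits
    P(repeat) = Φ(β′·ê + b̂) on that subset, returning b̂ with optional
    bootstrap uncertainty.  Raises if the conditioned subset is empty.
    """
    if "prev_response" not in session.columns:
        session = session.copy()
        session["prev_response"] = session.groupby("session_id", sort=False)["response"].shift(1)
    mask = match_history_pattern(session, pattern)
    mask &= session["response"].notna().to_numpy() & session["prev_response"].notna().to_numpy()
    if not mask.any():
        raise ValueError("no trials match the requested history pattern")
    sub = session.loc[mask]
    e = sub["evidence"].to_numpy(dtype=float)
    prev = sub["prev_response"].to_numpy(dtype=float)
    rep = (sub["response"].to_numpy(dtype=float) == prev).astype(float)
    return fit_probit(repeating_evidence(e, prev), rep, n_boot=n_boot, seed=seed, **kwargs)


def bias_buildup_curve(
    session: pd.DataFrame,
    max_n: int = 5,
    kind: str = "repetition",
    terminated_by_error: bool = False,
    n_boot: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeating bias b̂ versus length n of a correct run.

    For n = 1..max_n, conditions on n consecutive correct repetitions
    (or alternations), optionally terminated by an error, and tabulates
    the fitted bias — the build-up / reset curves of the repeating-bias
    analysis.
    """
    maker = repetition_pattern if kind == "repetition" else alternation_pattern
    rows = []
    for n in range(1, max_n + 1):
        fit = repeating_bias_conditioned(
            session, maker(n, terminated_by_error), n_boot=n_boot, seed=seed
        )
        rows.append(
            {
                "n": n,
                "kind": kind,
                "terminated_by_error": terminated_by_error,
                "bias": fit.bias,
                "sensitivity": fit.sensitivity,
                "bias_sd": fit.bias_sd,
                "n_trials": fit.n_trials,
                "stable": fit.stable,
            }
        )
    return pd.DataFrame(rows)
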