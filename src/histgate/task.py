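"""Block-structured 2AFC task generator.

The task presents, on each trial, an acoustic stimulus whose rewarded
category c_k ∈ {−1, +1} (left/right) follows a two-state Markov chain:
the category repeats the previous one with probability P_rep, which
switches between 0.7 ("repeating" blocks) and 0.2 ("alternating"
blocks) every 200 trials.  Stimulus difficulty is a strength
s_k ∈ {0, 0.23, 0.48, 1} drawn independently of the category; the signed
stimulus evidence is e_k = c_k · s_k.  Within a trial the stimulus is a
sequence of amplitude-modulation frames (one per 50 ms AM cycle at
20 Hz); the instantaneous evidence S_{k,f} of frame f is drawn from a
stretched beta distribution on [−1, 1] with mean e_k and fixed variance
(Dirac delta at ±1 when |e_k| = 1).  Frame evidence sets the two
envelope amplitude weights a^L = (1 + S)/2 and a^R = (1 − S)/2, which
sum to one in every frame.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REPEATING = "repeating"
ALTERNATING = "alternating"

__all__ = [
    "TaskConfig",
    "TrialStimulus",
    "generate_category_sequence",
    "generate_block_schedule",
    "stretched_beta_params",
    "sample_frame_evidence",
    "build_am_stimulus",
    "generate_stimulus_session",
    "REPEATING",
    "ALTERNATING",
]


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the block-structured stimulus sequence.

    Attributes
    ----------
    p_rep_repeating, p_rep_alternating
        Markov repeat probabilities in the two block types.
    block_length
        Trials per block before the repeat probability switches.
    strengths
        Allowed stimulus strengths (absolute evidence levels) in [0, 1],
        sampled uniformly and independently of the category.
    frame_variance
        Variance of the per-frame instantaneous evidence around e_k.
    n_frames
        Frames per trial; each frame spans one AM-envelope cycle.
    f_am
        Amplitude-modulation frequency in Hz (20 Hz → 50 ms cycles).
    phase
        AM phase delay in radians; 3π/2 makes the envelope zero at t = 0.
    first_block, initial_category
        Block type of the first block and category seeding the chain.
    rng_seed
        Seed of the single generator stream used for all draws.
    """

    p_rep_repeating: float = 0.7
    p_rep_alternating: float = 0.2
    block_length: int = 200
    strengths: tuple[float, ...] = (0.0, 0.23, 0.48, 1.0)
    frame_variance: float = 0.06
    n_frames: int = 8
    f_am: float = 20.0
    phase: float = 3 * np.pi / 2
    first_block: str = REPEATING
    initial_category: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_rep_repeating", "p_rep_alternating"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.block_length < 1:
            raise ValueError("block_length must be >= 1")
        if not all(0.0 <= s <= 1.0 for s in self.strengths):
            raise ValueError("strengths must lie in [0, 1]")
        if self.frame_variance <= 0:
            raise ValueError("frame_variance must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.first_block not in (REPEATING, ALTERNATING):
            raise ValueError(f"unknown block type {self.first_block!r}")
        if self.initial_category not in (-1, 1):
            raise ValueError("initial_category must be -1 or +1")

    def p_rep(self, block: str) -> float:
        return self.p_rep_repeating if block == REPEATING else self.p_rep_alternating

    def replace(self, **kwargs) -> "TaskConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TrialStimulus:
    """One trial's stimulus: category, strength and per-frame evidence."""

    category: int
    strength: float
    frames: np.ndarray = field(default_factory=lambda: np.empty(0))
    block: str = REPEATING

    @property
    def evidence(self) -> float:
        return self.category * self.strength


def generate_category_sequence(
    p_rep: float,
    n_trials: int,
    initial_category: int = 1,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Markov chain of stimulus categories c_k ∈ {−1, +1}.

    Each category repeats the previous one with probability ``p_rep`` and
    flips otherwise; the marginal over categories is uniform for any
    p_rep in (0, 1).
    """
    if not 0.0 <= p_rep <= 1.0:
        raise ValueError(f"p_rep must lie in [0, 1], got {p_rep}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if initial_category not in (-1, 1):
        raise ValueError("initial_category must be -1 or +1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    # flip indicators for trials 2..n; cumulative product of ±1 signs
    flips = rng.random(n_trials - 1) >= p_rep
    signs = np.where(flips, -1, 1)
    out = np.empty(n_trials, dtype=np.int8)
    out[0] = initial_category
    if n_trials > 1:
        out[1:] = initial_category * np.cumprod(signs)
    return out


def generate_block_schedule(
    config: TaskConfig, n_trials: int, first_block: str | None = None
) -> np.ndarray:
    """Per-trial block labels alternating every ``block_length`` trials."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    first = config.first_block if first_block is None else first_block
    if first not in (REPEATING, ALTERNATING):
        raise ValueError(f"unknown block type {first!r}")
    other = ALTERNATING if first == REPEATING else REPEATING
    block_idx = np.arange(n_trials) // config.block_length
    return np.where(block_idx % 2 == 0, first, other)


def stretched_beta_params(evidence: float, frame_variance: float) -> tuple[float, float]:
    """Shape parameters (α, β) of the beta on [0,1] mapped from [−1,1].

    x ∈ [−1, 1] is mapped to u = (x + 1)/2; the target mean is
    m = (e + 1)/2 and target variance v = frame_variance / 4.  Raises if
    the variance is infeasible for the requested mean (v ≥ m(1 − m)).
    """
    m = (evidence + 1.0) / 2.0
    v = frame_variance / 4.0
    if v >= m * (1.0 - m):
        raise ValueError(
            f"frame variance {frame_variance} infeasible for evidence {evidence}"
        )
    nu = m * (1.0 - m) / v - 1.0
    return m * nu, (1.0 - m) * nu


def sample_frame_evidence(
    evidence: float,
    n_frames: int,
    frame_variance: float = 0.06,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw per-frame instantaneous evidence S_f ∈ [−1, 1].

    For |evidence| = 1 the distribution degenerates to a point mass at
    ±1 (every frame equals the category); otherwise frames are i.i.d.
    stretched-beta with mean ``evidence`` and variance ``frame_variance``.
    """
    if abs(evidence) > 1.0:
        raise ValueError("evidence must lie in [-1, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if abs(evidence) == 1.0:
        return np.full(n_frames, float(evidence))
    a, b = stretched_beta_params(evidence, frame_variance)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return 2.0 * rng.beta(a, b, size=n_frames) - 1.0


def build_am_stimulus(
    frames: np.ndarray, config: TaskConfig, sample_rate: float = 4000.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Envelope amplitude weights and AM modulation of one stimulus.

    Frame f (1-based) covers the half-open interval
    [(f−1)/f_am, f/f_am); within it the envelope weights are constant,
    a^L = (1 + S_f)/2 and a^R = (1 − S_f)/2, so a^L + a^R = 1 at every
    sample.  The common modulation factor 1 + sin(2π f_am t + φ)
    vanishes at t = 0 for φ = 3π/2.

    Returns ``(envelope_left, envelope_right, modulation)`` sampled at
    ``sample_rate``.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.size == 0:
        raise ValueError("frames must be nonempty")
    if sample_rate <= 2 * config.f_am:
        raise ValueError("sample_rate must exceed twice the AM frequency")
    cycle = 1.0 / config.f_am
    n_samples = int(round(frames.size * cycle * sample_rate))
    t = np.arange(n_samples) / sample_rate
    frame_idx = np.minimum((t * config.f_am).astype(int), frames.size - 1)
    s = frames[frame_idx]
    # 0.5 ± 0.5·S keeps the sum bit-exactly 1 in floating point
    env_left = 0.5 + 0.5 * s
    env_right = 0.5 - 0.5 * s
    modulation = 1.0 + np.sin(2.0 * np.pi * config.f_am * t + config.phase)
    return env_left, env_right, modulation


def generate_stimulus_session(
    config: TaskConfig,
    n_trials: int,
    seed: int | None = None,
    session_id: str = "sim",
) -> pd.DataFrame:
    """Generate the stimulus side of a session as a SessionTable.

    Composes the block schedule, the Markov category chain (with the
    block-appropriate repeat probability on each trial), uniform
    strength draws and per-frame evidence.  Returns a DataFrame with the
    stimulus columns of the canonical session format; response/outcome
    columns are absent until an agent is simulated on it.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    blocks = generate_block_schedule(config, n_trials)
    p_rep = np.where(blocks == REPEATING, config.p_rep_repeating, config.p_rep_alternating)
    # category chain with per-trial repeat probability (block-dependent)
    flips = rng.random(n_trials) >= p_rep  # flips[0] unused
    categories = np.empty(n_trials, dtype=np.int8)
    categories[0] = config.initial_category
    signs = np.where(flips[1:], -1, 1)
    if n_trials > 1:
        categories[1:] = config.initial_category * np.cumprod(signs)
    strengths = rng.choice(np.asarray(config.strengths, dtype=float), size=n_trials)
    evidence = categories * strengths
    frames = np.empty((n_trials, config.n_frames))
    exact = np.abs(evidence) == 1.0
    frames[exact] = evidence[exact, None]
    for e in np.unique(evidence[~exact]):
        sel = (~exact) & (evidence == e)
        a, b = stretched_beta_params(float(e), config.frame_variance)
        frames[sel] = 2.0 * rng.beta(a, b, size=(int(sel.sum()), config.n_frames)) - 1.0
    table = pd.DataFrame(
        {
            "session_id": session_id,
            "trial_index": np.arange(1, n_trials + 1),
            "block": blocks,
            "category": categories.astype(int),
            "strength": strengths,
            "evidence": evidence,
        }
    )
    for f in range(config.n_frames):
        table[f"frame_{f + 1}"] = frames[:, f]
    return table
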