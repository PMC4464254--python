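"""Mean-variance valuation of the four decks with softmax choice.

For a deck showing card value x with scaled payoffs W (win) and L (loss
magnitude), and win probability p = P(first card beats second | x):

    reward prediction   r_hat = p*W - (1-p)*L
    risk prediction     Risk  = p*(1-p)*(W+L)**2      (two-outcome variance)
    utility             U     = r_hat + l*Risk

where ``l`` in [-1, 1] is the subject's risk preference (negative =
risk-averse).  Choice probabilities follow a temperature-free softmax over
the four utilities; Shannon entropy of those probabilities measures the
difficulty of the choice comparison.

Points are divided by ``payoff_scale`` (default 125, the largest payoff
magnitude) before valuation so utilities are O(1); without a softmax
temperature this scale is what keeps choice probabilities away from the
deterministic regime.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .task import TaskSequence, win_probability

LN4 = float(np.log(4.0))

L_BOUNDS = (-1.0, 1.0)


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Risk preference and the payoff scaling applied before valuation."""

    risk_preference: float = 0.0
    payoff_scale: float = 125.0
    #: weight risk as standard deviation instead of variance (off by default)
    risk_as_sd: bool = False

    def __post_init__(self) -> None:
        if not (L_BOUNDS[0] <= self.risk_preference <= L_BOUNDS[1]):
            raise ValueError(f"risk_preference must lie in {L_BOUNDS}")
        if self.payoff_scale <= 0:
            raise ValueError("payoff_scale must be positive")


@dataclasses.dataclass(frozen=True)
class TrialValuation:
    """Per-deck valuations and the softmax choice distribution for one trial."""

    expected_reward: np.ndarray  # (4,) scaled points
    risk_prediction: np.ndarray  # (4,) scaled points squared
    utility: np.ndarray  # (4,)
    choice_probabilities: np.ndarray  # (4,), sums to 1
    entropy: float  # nats, in [0, ln 4]


def reward_prediction(p, W, L):
    """Expected scaled payoff p*W - (1-p)*L; L is a positive loss magnitude."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("win probability must lie in [0, 1]")
    out = p * W - (1.0 - p) * L
    return float(out) if out.ndim == 0 else out


def risk_prediction(p, W, L):
    """Two-outcome payoff variance p*(1-p)*(W+L)^2 (the closed form)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("win probability must lie in [0, 1]")
    out = p * (1.0 - p) * (W + L) ** 2
    return float(out) if out.ndim == 0 else out


def utility(expected_reward, risk, l: float):
    """Mean-variance utility: expected reward plus l times predicted risk."""
    risk_arr = np.asarray(risk, dtype=float)
    if np.any(risk_arr < 0):
        raise ValueError("risk must be non-negative")
    out = np.asarray(expected_reward, dtype=float) + l * risk_arr
    return float(out) if out.ndim == 0 else out


def choice_probabilities(utilities) -> np.ndarray:
    """Temperature-free softmax over deck utilities (max-subtracted)."""
    u = np.asarray(utilities, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("utilities must be finite")
    z = u - u.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def trial_entropy(probabilities) -> float:
    """Shannon entropy -sum p ln p in nats, with 0*ln(0) == 0."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("probabilities must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def deck_moments(task: TaskSequence, payoff_scale: float = 125.0):
    """Per-trial, per-deck (expected reward, risk prediction), both (n, 4).

    These are the l-independent ingredients of the utility; computing them
    once lets the likelihood be evaluated cheaply over many candidate l.
    """
    p = win_probability(task.values)
    W = task.win_payoffs() / payoff_scale
    L = task.loss_payoffs() / payoff_scale
    e = reward_prediction(p, W[None, :], L[None, :])
    v = risk_prediction(p, W[None, :], L[None, :])
    return e, v


def valuate_trial(values_row, deck_specs, params: ModelParams) -> TrialValuation:
    """Full valuation of one trial's four decks under ``params``."""
    p = win_probability(np.asarray(values_row))
    W = np.array([d.win_points for d in deck_specs], dtype=float) / params.payoff_scale
    L = np.array([d.loss_points for d in deck_specs], dtype=float) / params.payoff_scale
    e = reward_prediction(p, W, L)
    v = risk_prediction(p, W, L)
    risk_term = np.sqrt(v) if params.risk_as_sd else v
    u = utility(e, risk_term, params.risk_preference)
    probs = choice_probabilities(u)
    return TrialValuation(
        expected_reward=e,
        risk_prediction=v,
        utility=u,
        choice_probabilities=probs,
        entropy=trial_entropy(probs),
    )


def valuate_sequence(task: TaskSequence, params: ModelParams) -> pd.DataFrame:
    """Tidy per-trial x per-deck valuation table (for regressor building).

    Columns: trial, deck, expected_reward, risk_prediction, utility,
    choice_probability, plus a per-trial entropy column repeated per deck.
    """
    e, v = deck_moments(task, params.payoff_scale)
    risk_term = np.sqrt(v) if params.risk_as_sd else v
    u = e + params.risk_preference * risk_term
    probs = choice_probabilities(u)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(probs)
    ent = -(np.where(probs > 0, probs * logp, 0.0)).sum(axis=1)
    n = task.n_trials
    df = pd.DataFrame(
        {
            "trial": np.repeat(np.arange(1, n + 1), 4),
            "deck": np.tile(list("ABCD"), n),
            "expected_reward": e.ravel(),
            "risk_prediction": v.ravel(),
            "utility": u.ravel(),
            "choice_probability": probs.ravel(),
            "entropy": np.repeat(ent, 4),
        }
    )
    return df


def trial_modulators(task: TaskSequence, params: ModelParams, choices=None):
    """Per-trial regressor amplitudes: risk, reward and entropy.

    With ``choices`` (deck indices, one per trial) the risk and reward
    modulators are the chosen deck's risk and reward predictions — the
    quantities whose outcome the trial actually resolves.  Without choices
    they fall back to probability-weighted deck averages.  Entropy is the
    trial's choice difficulty either way.  Returns a dict of (n,) arrays.
    """
    e, v = deck_moments(task, params.payoff_scale)
    risk_term = np.sqrt(v) if params.risk_as_sd else v
    u = e + params.risk_preference * risk_term
    probs = choice_probabilities(u)
    ent = -(probs * np.log(probs)).sum(axis=1)  # softmax probs are strictly positive
    if choices is not None:
        choices = np.asarray(choices, dtype=int)
        idx = np.arange(task.n_trials)
        risk_mod, reward_mod = v[idx, choices], e[idx, choices]
    else:
        risk_mod, reward_mod = (probs * v).sum(axis=1), (probs * e).sum(axis=1)
    return {"risk": risk_mod, "reward": reward_mod, "entropy": ent}
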