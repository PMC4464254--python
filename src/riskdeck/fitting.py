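"""Maximum-likelihood estimation of risk preference and fit statistics.

One free parameter l (risk preference) is fitted per choice dataset by
maximising the summed log-likelihood of the observed deck choices under the
softmax model.  The search is an even grid over [-1, 1] (1000 steps by
default) followed by seeded golden-section refinements, which is globally
exact here: each trial's log choice probability is a log-softmax of
utilities affine in l, hence concave, and the summed log-likelihood has a
single maximum.

Fit quality is summarised the way behavioural model-comparison tables
conventionally report it at per-trial scale:

    MLL  = -LL / n_trials                (mean negative log-likelihood, nats/trial)
    AIC  = 2k + 2*MLL
    AICc = AIC + 2k(k+1) / (M - k - 1)
    BIC  = k*ln(M) + 2*MLL

with k = 1 free parameter and M the number of datasets in the comparison
group (e.g. 30 subjects, or 1000 simulated random agents) — an unusual but
deliberate convention in which the small-sample and Bayesian penalties are
taken at group size; M is always explicit.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy import optimize, stats

from .model import L_BOUNDS, deck_moments
from .task import ChoiceDataset


@dataclasses.dataclass(frozen=True)
class SearchConfig:
    """Grid-plus-restarts search settings for the 1-D likelihood maximisation."""

    n_grid_steps: int = 1000
    n_restarts: int = 4
    bounds: tuple[float, float] = L_BOUNDS
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_grid_steps < 2:
            raise ValueError("n_grid_steps must be >= 2")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("bounds must be ordered (low, high)")


@dataclasses.dataclass(frozen=True)
class FitResult:
    l_hat: float
    mll: float  # per-trial mean negative log-likelihood, nats/trial
    aic: float
    aicc: float
    bic: float
    accuracy: float
    n_trials: int
    k_params: int = 1
    group_size: int = 30

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _log_choice_prob_grid(e, v, choices, ls):
    """Summed log-likelihood at each candidate l.

    e, v: (n, 4) reward/risk moments; choices: (n,) deck indices;
    ls: (L,) candidate risk preferences.  Returns (L,) log-likelihoods.
    """
    ls = np.atleast_1d(np.asarray(ls, dtype=float))
    u = e[None, :, :] + ls[:, None, None] * v[None, :, :]  # (L, n, 4)
    m = u.max(axis=2)
    lse = m + np.log(np.exp(u - m[:, :, None]).sum(axis=2))
    n = len(choices)
    chosen = u[:, np.arange(n), choices]
    return (chosen - lse).sum(axis=1)


def _neg_ll_scalar(e, v, idx, choices, l: float) -> float:
    """Fast single-l negative log-likelihood (max-subtracted softmax)."""
    u = e + l * v
    m = u.max(axis=1)
    lse = m + np.log(np.exp(u - m[:, None]).sum(axis=1))
    return float((lse - u[idx, choices]).sum())


def log_likelihood(dataset: ChoiceDataset, l: float, payoff_scale: float = 125.0) -> float:
    """Summed ln P(chosen deck) over trials under the model at l (always <= 0)."""
    if dataset.n_trials == 0:
        raise ValueError("dataset has no trials")
    e, v = deck_moments(dataset.task, payoff_scale)
    return float(_log_choice_prob_grid(e, v, dataset.choices, [l])[0])


def fit_risk_preference(
    dataset: ChoiceDataset,
    search: SearchConfig | None = None,
    payoff_scale: float = 125.0,
    group_size: int = 30,
) -> FitResult:
    """Fit l in [-1, 1] by maximum likelihood (grid + seeded refinements)."""
    if dataset.n_trials == 0:
        raise ValueError("dataset has no trials")
    search = search or SearchConfig()
    e, v = deck_moments(dataset.task, payoff_scale)
    choices = np.asarray(dataset.choices, dtype=int)

    lo, hi = search.bounds
    grid = np.linspace(lo, hi, search.n_grid_steps + 1)
    ll_grid = _log_choice_prob_grid(e, v, choices, grid)
    best = int(np.argmax(ll_grid))

    idx = np.arange(len(choices))

    def neg_ll(l: float) -> float:
        return _neg_ll_scalar(e, v, idx, choices, l)

    # local golden-section refinements: the best grid neighborhood plus
    # n_restarts seeded draws from the top of the grid ranking
    rng = np.random.default_rng(search.rng_seed)
    order = np.argsort(ll_grid)[::-1]
    top = order[: max(10, search.n_restarts)]
    starts = [best] + [int(i) for i in rng.choice(top, size=search.n_restarts)]
    candidates: list[tuple[float, float]] = []
    for i in dict.fromkeys(starts):  # dedupe, order-preserving
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            neg_ll, bounds=(a, b), method="bounded", options={"xatol": 1e-6}
        )
        candidates.append((float(res.fun), float(res.x)))
    candidates.extend((float(-ll_grid[i]), float(grid[i])) for i in starts)
    best_fun = min(c[0] for c in candidates)
    # tie-break toward smallest |l| among numerically equal optima
    l_hat = min(
        (c[1] for c in candidates if c[0] <= best_fun + 1e-12), key=abs
    )

    n = dataset.n_trials
    mll = float(-_log_choice_prob_grid(e, v, choices, [l_hat])[0] / n)
    aic, aicc, bic = information_criteria(mll, k=1, M=group_size)
    acc = prediction_accuracy(dataset, l_hat, payoff_scale)
    return FitResult(
        l_hat=float(l_hat),
        mll=mll,
        aic=aic,
        aicc=aicc,
        bic=bic,
        accuracy=acc,
        n_trials=n,
        k_params=1,
        group_size=group_size,
    )


def prediction_accuracy(
    dataset: ChoiceDataset, l_hat: float, payoff_scale: float = 125.0
) -> float:
    """Fraction of trials whose argmax-probability deck matches the choice.

    Ties broken toward the lowest deck index (A < B < C < D).
    """
    e, v = deck_moments(dataset.task, payoff_scale)
    u = e + l_hat * v
    predicted = np.argmax(u, axis=1)  # argmax of utility == argmax of softmax prob
    return float(np.mean(predicted == dataset.choices))


def information_criteria(mll: float, k: int, M: int) -> tuple[float, float, float]:
    """(AIC, AICc, BIC) under the per-trial MLL / group-size-M convention."""
    if mll < 0:
        raise ValueError("mll is a mean negative log-likelihood and must be >= 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    if M <= k + 1:
        raise ValueError("group size M must exceed k + 1")
    aic = 2.0 * k + 2.0 * mll
    aicc = aic + 2.0 * k * (k + 1) / (M - k - 1)
    bic = k * float(np.log(M)) + 2.0 * mll
    return aic, aicc, bic


_FIT_STATS = ("mll", "aic", "aicc", "bic")


def compare_fit_groups(fits_a, fits_b) -> dict[str, dict[str, float]]:
    """Independent-samples (pooled-variance) t-test per fit statistic.

    Returns {stat: {mean_a, sd_a, mean_b, sd_b, t, p}} for MLL/AIC/AICc/BIC.
    """
    if len(fits_a) < 2 or len(fits_b) < 2:
        raise ValueError("each group needs at least 2 fits")
    out: dict[str, dict[str, float]] = {}
    for stat in _FIT_STATS:
        a = np.array([getattr(f, stat) for f in fits_a], dtype=float)
        b = np.array([getattr(f, stat) for f in fits_b], dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        out[stat] = {
            "mean_a": float(a.mean()),
            "sd_a": float(a.std(ddof=1)),
            "mean_b": float(b.mean()),
            "sd_b": float(b.std(ddof=1)),
            "t": float(t),
            "p": float(p),
        }
    return out
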