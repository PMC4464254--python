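"""Four-deck probabilistic card task: stimuli, payoff schedule, outcomes.

Each trial shows one face-up card per deck, its value drawn from the
21-value universe {0, 5, ..., 100}.  Choosing a deck reveals a second card
drawn from the same universe but never equal to the first; the trial is won
if the first card beats the second.  Decks A and B pay +100 / -125 points,
decks C and D pay +50 / -25, so the A/B pair is the high-stakes
(high-variance) option at every card value.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

#: The arithmetic sequence of admissible card values.
CARD_VALUES = np.arange(0, 101, 5)
N_CARD_VALUES = len(CARD_VALUES)  # 21
DECK_NAMES = ("A", "B", "C", "D")


@dataclasses.dataclass(frozen=True)
class DeckSpec:
    """Payoff schedule of one deck.

    ``loss_points`` is a positive magnitude; a lost trial subtracts it.
    """

    deck_id: str
    win_points: int
    loss_points: int

    def __post_init__(self) -> None:
        if self.deck_id not in DECK_NAMES:
            raise ValueError(f"deck_id must be one of {DECK_NAMES}, got {self.deck_id!r}")
        if self.win_points <= 0 or self.loss_points <= 0:
            raise ValueError("win_points and loss_points must be positive magnitudes")


def default_deck_specs() -> tuple[DeckSpec, DeckSpec, DeckSpec, DeckSpec]:
    """High-stakes A/B (+100/-125) and low-stakes C/D (+50/-25) decks."""
    return (
        DeckSpec("A", 100, 125),
        DeckSpec("B", 100, 125),
        DeckSpec("C", 50, 25),
        DeckSpec("D", 50, 25),
    )


@dataclasses.dataclass(frozen=True)
class TaskSequence:
    """An ordered stimulus sequence: one shown card value per deck per trial.

    ``values`` has shape (n_trials, 4), columns in deck order A..D, every
    entry in :data:`CARD_VALUES`.  Invariants: value(A) != value(B) and
    value(C) != value(D) within each trial; within each deck, consecutive
    trials never repeat a value.
    """

    values: np.ndarray
    deck_specs: tuple[DeckSpec, DeckSpec, DeckSpec, DeckSpec]
    rng_seed: int | None = None

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def win_payoffs(self) -> np.ndarray:
        return np.array([d.win_points for d in self.deck_specs], dtype=float)

    def loss_payoffs(self) -> np.ndarray:
        return np.array([d.loss_points for d in self.deck_specs], dtype=float)

    def validate(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[1] != 4:
            raise ValueError("values must have shape (n_trials, 4)")
        if not np.isin(v, CARD_VALUES).all():
            raise ValueError("card values must lie in {0, 5, ..., 100}")
        if np.any(v[:, 0] == v[:, 1]) or np.any(v[:, 2] == v[:, 3]):
            raise ValueError("A/B and C/D must show different values within a trial")
        if v.shape[0] > 1 and np.any(v[1:] == v[:-1]):
            raise ValueError("consecutive trials must not repeat a value within a deck")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"val{d}" for d in DECK_NAMES])
        df.insert(0, "trial", np.arange(1, self.n_trials + 1))
        return df


@dataclasses.dataclass(frozen=True)
class OutcomeRecord:
    """Realized result of one chosen trial."""

    trial_index: int
    chosen_deck: int  # 0-based deck index, 0..3
    second_card_value: int
    won: bool
    points_delta: int


@dataclasses.dataclass
class ChoiceDataset:
    """One agent's (or subject's) full run of the task.

    ``choices`` are 0-based deck indices, ``deltas`` signed point outcomes.
    """

    task: TaskSequence
    choices: np.ndarray
    second_cards: np.ndarray
    deltas: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.choices)

    def total_score(self) -> float:
        return float(np.sum(self.deltas))

    def to_frame(self) -> pd.DataFrame:
        df = self.task.to_frame()
        df["choice"] = [DECK_NAMES[c] for c in self.choices]
        df["second_card"] = self.second_cards
        df["delta"] = self.deltas
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, deck_specs=None) -> "ChoiceDataset":
        df = pd.read_csv(path)
        specs = tuple(deck_specs) if deck_specs is not None else default_deck_specs()
        task = TaskSequence(
            values=df[[f"val{d}" for d in DECK_NAMES]].to_numpy(dtype=int),
            deck_specs=specs,
        )
        choices = np.array([DECK_NAMES.index(c) for c in df["choice"]])
        return cls(
            task=task,
            choices=choices,
            second_cards=df["second_card"].to_numpy(dtype=int),
            deltas=df["delta"].to_numpy(dtype=int),
        )


def generate_task_sequence(
    n_trials: int = 180,
    deck_specs: Sequence[DeckSpec] | None = None,
    rng_seed: int = 0,
) -> TaskSequence:
    """Generate a stimulus sequence satisfying the task's display constraints.

    First-card values are uniform over the admissible set given the two
    constraints (A != B and C != D within a trial; no per-deck repeat
    across consecutive trials), realized by per-deck rejection against the
    previous trial.  Deterministic for a fixed ``rng_seed``.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    specs = tuple(deck_specs) if deck_specs is not None else default_deck_specs()
    if len(specs) != 4:
        raise ValueError("exactly four deck specs are required")
    rng = np.random.default_rng(rng_seed)
    values = np.empty((n_trials, 4), dtype=int)
    prev = None
    for t in range(n_trials):
        row = np.empty(4, dtype=int)
        for pair in ((0, 1), (2, 3)):
            while True:
                cand = rng.choice(CARD_VALUES, size=2, replace=False)
                if prev is not None and (
                    cand[0] == prev[pair[0]] or cand[1] == prev[pair[1]]
                ):
                    continue
                row[pair[0]], row[pair[1]] = cand
                break
        values[t] = row
        prev = row
    seq = TaskSequence(values=values, deck_specs=specs, rng_seed=rng_seed)
    seq.validate()
    return seq


def win_probability(card_value) -> np.ndarray | float:
    """Probability that a shown card beats the hidden second card.

    The second card is uniform over the 20 universe values different from
    the shown one, so P(win) = (# values strictly below) / 20.  Accepts a
    scalar or array of card values.
    """
    v = np.asarray(card_value)
    if not np.isin(v, CARD_VALUES).all():
        raise ValueError("card value(s) must lie in {0, 5, ..., 100}")
    p = (v // 5) / (N_CARD_VALUES - 1)
    return float(p) if np.isscalar(card_value) else p


def realize_outcome(
    values_row: np.ndarray,
    chosen_deck: int,
    rng: np.random.Generator,
    deck_specs: Sequence[DeckSpec] | None = None,
    trial_index: int = 1,
) -> OutcomeRecord:
    """Draw the second card and settle the chosen deck's payoff."""
    if chosen_deck not in range(4):
        raise ValueError("chosen_deck must be a deck index in 0..3")
    specs = tuple(deck_specs) if deck_specs is not None else default_deck_specs()
    first = int(values_row[chosen_deck])
    admissible = CARD_VALUES[CARD_VALUES != first]
    second = int(rng.choice(admissible))
    won = first > second
    delta = specs[chosen_deck].win_points if won else -specs[chosen_deck].loss_points
    return OutcomeRecord(
        trial_index=trial_index,
        chosen_deck=chosen_deck,
        second_card_value=second,
        won=won,
        points_delta=int(delta),
    )


def realize_outcomes(
    task: TaskSequence, choices: np.ndarray, rng: np.random.Generator
) -> ChoiceDataset:
    """Vectorised outcome realization for a full choice sequence."""
    choices = np.asarray(choices, dtype=int)
    n = task.n_trials
    if len(choices) != n:
        raise ValueError("one choice per trial is required")
    first = task.values[np.arange(n), choices]
    # second card: uniform over the 20 values != first
    draw = rng.integers(0, N_CARD_VALUES - 1, size=n)
    second = CARD_VALUES[draw + (CARD_VALUES[draw] >= first)]
    won = first > second
    wins = task.win_payoffs()[choices]
    losses = task.loss_payoffs()[choices]
    deltas = np.where(won, wins, -losses).astype(int)
    return ChoiceDataset(task=task, choices=choices, second_cards=second, deltas=deltas)


def total_score(outcomes) -> float:
    """Sum of signed point outcomes over a list of :class:`OutcomeRecord`."""
    return float(sum(o.points_delta for o in outcomes))
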