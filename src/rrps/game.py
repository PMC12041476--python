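"""Hands, outcomes, cyclic-dominance algebra, and the round/game data model.

Everything downstream (the AI opponent, rule detection, feature extraction)
consumes the integer encodings defined here:

* hands      R=0, P=1, S=2       (rock, paper, scissors)
* outcomes   W=0, T=1, L=2       (win, tie, lose -- player's perspective)
* transitions D=0, C=1, U=2      (downgrade, copy, upgrade w.r.t. a reference)

Cyclic dominance: rock beats scissors, paper beats rock, scissors beats
paper; equivalently the hand ``(h + 1) % 3`` beats ``h``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "Hand",
    "Outcome",
    "Transition",
    "Round",
    "GameRecord",
    "outcome",
    "outcome_array",
    "transition",
    "transition_array",
    "apply_transition",
    "beats",
]


class Hand(IntEnum):
    """One of the three hands, cyclically ordered so ``(h + 1) % 3`` beats ``h``."""

    R = 0
    P = 1
    S = 2

    @classmethod
    def from_symbol(cls, s: str) -> "Hand":
        try:
            return cls[s.strip().upper()]
        except KeyError:
            raise ValueError(f"invalid hand symbol {s!r}; expected one of R, P, S") from None


class Outcome(IntEnum):
    """Round outcome from the player's perspective: win, tie or lose."""

    W = 0
    T = 1
    L = 2

    @classmethod
    def from_symbol(cls, s: str) -> "Outcome":
        try:
            return cls[s.strip().upper()]
        except KeyError:
            raise ValueError(f"invalid outcome symbol {s!r}; expected one of w, t, l") from None


class Transition(IntEnum):
    """Move relative to a reference hand: Downgrade (loses to it), Copy, Upgrade (beats it)."""

    D = 0
    C = 1
    U = 2


def beats(h: Hand | int) -> Hand:
    """The hand that beats ``h``."""
    return Hand((int(h) + 1) % 3)


def outcome(hp: Hand | int, ai: Hand | int) -> Outcome:
    """Outcome of a round from the player's perspective under cyclic dominance."""
    # d == 0 tie; d == 1 player's hand beats opponent's; d == 2 it loses.
    return _OUTCOME_FROM_DIFF[(int(hp) - int(ai)) % 3]


_OUTCOME_FROM_DIFF = (Outcome.T, Outcome.W, Outcome.L)
_TRANSITION_FROM_DIFF = (Transition.C, Transition.U, Transition.D)


def outcome_array(hp: np.ndarray, ai: np.ndarray) -> np.ndarray:
    """Vectorized :func:`outcome` over integer hand arrays."""
    d = (np.asarray(hp, dtype=np.int64) - np.asarray(ai, dtype=np.int64)) % 3
    return _OUT_LUT[d]


_OUT_LUT = np.array([Outcome.T, Outcome.W, Outcome.L], dtype=np.int8)
_TRANS_LUT = np.array([Transition.C, Transition.U, Transition.D], dtype=np.int8)


def transition(reference: Hand | int, nxt: Hand | int) -> Transition:
    """Classify ``nxt`` relative to ``reference``: U if it beats it, C if equal, D if it loses."""
    return _TRANSITION_FROM_DIFF[(int(nxt) - int(reference)) % 3]


def transition_array(reference: np.ndarray, nxt: np.ndarray) -> np.ndarray:
    """Vectorized :func:`transition` over integer hand arrays."""
    d = (np.asarray(nxt, dtype=np.int64) - np.asarray(reference, dtype=np.int64)) % 3
    return _TRANS_LUT[d]


def apply_transition(reference: Hand | int, t: Transition | int) -> Hand:
    """Inverse of :func:`transition`: the hand standing in relation ``t`` to ``reference``."""
    offset = {Transition.D: 2, Transition.C: 0, Transition.U: 1}[Transition(int(t))]
    return Hand((int(reference) + offset) % 3)


@dataclass(frozen=True)
class Round:
    """A single resolved round. ``index`` is 1-based; outcome is derived from the hands."""

    index: int
    hp_hand: Hand
    ai_hand: Hand
    outcome: Outcome
    response_time: float  # milliseconds
    wall_time: Optional[float] = None  # seconds since game start

    def __post_init__(self) -> None:
        if self.outcome != outcome(self.hp_hand, self.ai_hand):
            raise ValueError(
                f"round {self.index}: outcome {self.outcome.name} inconsistent with hands "
                f"{self.hp_hand.name} vs {self.ai_hand.name}"
            )
        if self.response_time < 0:
            raise ValueError(f"round {self.index}: negative response time")


@dataclass
class GameRecord:
    """An ordered 300-round (by default) game of one player against the AI.

    Array-backed: ``hp``, ``ai`` are int8 hand codes, ``out`` the derived
    outcome codes, ``rt_ms`` response times, ``wall_s`` optional wall-clock
    offsets.  ``metadata`` carries player type, seeds, AI parameters, the
    per-round AI confidence (key ``"ai_confidence"``, shape (n, 3)) and, for
    simulated rule-switchers, ground-truth switch rounds
    (key ``"true_switch_rounds"``).
    """

    player_id: str
    hp: np.ndarray
    ai: np.ndarray
    rt_ms: np.ndarray
    wall_s: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)
    out: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.hp = np.asarray(self.hp, dtype=np.int8)
        self.ai = np.asarray(self.ai, dtype=np.int8)
        self.rt_ms = np.asarray(self.rt_ms, dtype=np.float64)
        if self.wall_s is not None:
            self.wall_s = np.asarray(self.wall_s, dtype=np.float64)
        if not (len(self.hp) == len(self.ai) == len(self.rt_ms)):
            raise ValueError("hp, ai and rt_ms must have equal length")
        if self.wall_s is not None and len(self.wall_s) != len(self.hp):
            raise ValueError("wall_s length mismatch")
        if len(self.hp) == 0:
            raise ValueError("a game must contain at least one round")
        for name, arr in (("hp", self.hp), ("ai", self.ai)):
            if arr.min() < 0 or arr.max() > 2:
                raise ValueError(f"{name} contains invalid hand codes")
        self.out = outcome_array(self.hp, self.ai)

    def __len__(self) -> int:
        return len(self.hp)

    @property
    def n_rounds(self) -> int:
        return len(self.hp)

    @property
    def net_wins(self) -> int:
        """#wins - #losses over the whole game."""
        return int(np.sum(self.out == Outcome.W) - np.sum(self.out == Outcome.L))

    def rounds(self) -> Iterator[Round]:
        """Yield :class:`Round` views (1-based indices)."""
        for k in range(len(self.hp)):
            yield Round(
                index=k + 1,
                hp_hand=Hand(int(self.hp[k])),
                ai_hand=Hand(int(self.ai[k])),
                outcome=Outcome(int(self.out[k])),
                response_time=float(self.rt_ms[k]),
                wall_time=None if self.wall_s is None else float(self.wall_s[k]),
            )

    def permuted(self, perm: np.ndarray) -> "GameRecord":
        """A copy with whole rounds re-ordered by ``perm`` (used by shuffle nulls).

        Within-round (hp, ai, outcome, rt) triples stay intact; metadata that
        is tied to round order is dropped.
        """
        return GameRecord(
            player_id=self.player_id,
            hp=self.hp[perm],
            ai=self.ai[perm],
            rt_ms=self.rt_ms[perm],
            wall_s=None if self.wall_s is None else self.wall_s[perm],
            metadata={"shuffled_from": self.player_id},
        )
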