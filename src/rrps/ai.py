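"""The exploiting opponent: three online perceptrons predicting the player's next hand.

One perceptron per hand (R, P, S) scores a 13-dimensional input -- one-hot
codes of the last two player hands and the last two AI hands (4 blocks of 3)
plus a constant bias.  The AI predicts the player's next hand as the argmax
of the three scores and plays the hand that beats the prediction.  After the
round resolves, each perceptron is updated online by the logistic delta rule
with target 1 for the hand the player actually produced and 0 for the other
two.  During the first two rounds no 2-round history exists and the AI plays
uniformly at random.

The relative magnitudes of the three scores double as a decision-confidence
readout; :meth:`PerceptronAI.confidence` exposes their softmax, which the
feature stage aggregates per lag-1 condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .game import Hand, beats

__all__ = ["PerceptronAI", "encode_history", "N_INPUTS"]

N_INPUTS = 13  # 4 one-hot hand blocks of 3, plus bias


def encode_history(hp_hands, ai_hands) -> np.ndarray:
    """One-hot encode the last two player and last two AI hands (+ bias).

    ``hp_hands`` and ``ai_hands`` each hold the two most recent hands in
    chronological order.  The result has exactly five ones (4 indicators +
    bias) and preserves positional information: blocks are
    (hp[-2], hp[-1], ai[-2], ai[-1]).

    Raises ``ValueError`` if fewer than two prior rounds are available
    (cold start -- the caller must fall back to random play).
    """
    hp_hands = list(hp_hands)
    ai_hands = list(ai_hands)
    if len(hp_hands) < 2 or len(ai_hands) < 2:
        raise ValueError("cold start: need 2 prior rounds from each side")
    x = np.zeros(N_INPUTS)
    for block, hand in enumerate(hp_hands[-2:] + ai_hands[-2:]):
        x[3 * block + int(hand)] = 1.0
    x[12] = 1.0
    return x


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


@dataclass
class PerceptronAI:
    """Three-perceptron opponent with online delta-rule learning.

    Parameters
    ----------
    learning_rate:
        Delta-rule step size (eta); must be positive or zero.
    rng_seed:
        Seed for the AI's private RNG (cold-start moves, argmax tie-breaks).
    """

    learning_rate: float = 0.1
    rng_seed: int = 0
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.zeros((3, N_INPUTS))
        self.rng = np.random.default_rng(self.rng_seed)
        self._hp_hist: list[int] = []
        self._ai_hist: list[int] = []

    # -- inference ---------------------------------------------------------

    def _input(self) -> np.ndarray | None:
        if len(self._hp_hist) < 2:
            return None
        return encode_history(self._hp_hist[-2:], self._ai_hist[-2:])

    def scores(self) -> np.ndarray | None:
        """Raw perceptron outputs for the current history, or None pre-history."""
        x = self._input()
        if x is None:
            return None
        return self.weights @ x

    def confidence(self) -> np.ndarray:
        """Softmax of the three scores; uniform during cold start."""
        s = self.scores()
        if s is None:
            return np.full(3, 1.0 / 3.0)
        return _softmax(s)

    def predict(self) -> Hand:
        """Predicted player hand: argmax score, ties broken uniformly at random."""
        s = self.scores()
        if s is None:
            return Hand(int(self.rng.integers(3)))
        winners = np.flatnonzero(s == s.max())
        if len(winners) > 1:
            return Hand(int(self.rng.choice(winners)))
        return Hand(int(winners[0]))

    def choose_move(self) -> Hand:
        """The AI's committed hand: strict best response to its prediction."""
        return beats(self.predict())

    # -- learning ----------------------------------------------------------

    def update(self, actual_hp_hand: Hand | int) -> None:
        """Observe the player's resolved hand; delta-rule update, then extend history.

        Called once per round with the hand the player just produced.  The AI's
        own committed hand must be appended via :meth:`record_own_move` by the
        game loop (``play_game`` does both).
        """
        x = self._input()
        if x is not None and self.learning_rate != 0.0:
            target = np.zeros(3)
            target[int(actual_hp_hand)] = 1.0
            pred = _sigmoid(self.weights @ x)
            self.weights += self.learning_rate * (target - pred)[:, None] * x[None, :]
        self._hp_hist.append(int(actual_hp_hand))

    def record_own_move(self, own_hand: Hand | int) -> None:
        self._ai_hist.append(int(own_hand))

    def reset(self) -> None:
        """Zero the weights and clear history (RNG state is preserved)."""
        self.weights[:] = 0.0
        self._hp_hist.clear()
        self._ai_hist.clear()
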