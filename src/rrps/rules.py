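"""The lag-1 rule space: 6 frameworks x 9 rules, and game -> observation conversion.

A lag-1 rule is "take action Y if condition X occurred in the previous
round".  Conditions are drawn from one of three classes -- the player's own
previous hand (r, p, s), the AI's previous hand (r_A, p_A, s_A), or the
previous outcome (w, t, l) -- and actions from one of three classes -- the
next hand itself (R, P, S), or the transition relative to the player's
(D, C, U) or the AI's (D_A, C_A, U_A) previous hand.  Not every pairing is
distinct (a hand-action rule set conditioned on the own hand restates a
transition-action one), leaving 6 canonical frameworks of 3 x 3 = 9 rules
each: 54 rules in all.

The canonical ordering fixed here defines the feature vocabulary used by
every downstream CSV, so it must never change.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator

import numpy as np
import pandas as pd

from .game import GameRecord, transition_array

__all__ = [
    "ConditionClass",
    "ActionClass",
    "Framework",
    "Rule",
    "FRAMEWORKS",
    "RULES",
    "enumerate_rules",
    "condition_array",
    "action_array",
    "extract_observations",
    "static_conditional_probs",
]


class ConditionClass(Enum):
    """What the previous round is summarized by."""

    OWN_HAND = "rps"
    AI_HAND = "r_A p_A s_A"
    OUTCOME = "wtl"


class ActionClass(Enum):
    """How the player's current move is coded."""

    HAND = "RPS"
    OWN_TRANSITION = "DCU"
    AI_TRANSITION = "D_A C_A U_A"


_CONDITION_SYMBOLS = {
    ConditionClass.OWN_HAND: ("r", "p", "s"),
    ConditionClass.AI_HAND: ("r_A", "p_A", "s_A"),
    ConditionClass.OUTCOME: ("w", "t", "l"),
}
_ACTION_SYMBOLS = {
    ActionClass.HAND: ("R", "P", "S"),
    ActionClass.OWN_TRANSITION: ("D", "C", "U"),
    ActionClass.AI_TRANSITION: ("D_A", "C_A", "U_A"),
}


@dataclass(frozen=True)
class Framework:
    """A (condition class, action class) pairing; exactly 6 are canonical."""

    condition_class: ConditionClass
    action_class: ActionClass

    @property
    def name(self) -> str:
        return f"{self.action_class.value}|{self.condition_class.value}"

    def condition_symbols(self) -> tuple[str, str, str]:
        return _CONDITION_SYMBOLS[self.condition_class]

    def action_symbols(self) -> tuple[str, str, str]:
        return _ACTION_SYMBOLS[self.action_class]

    def __repr__(self) -> str:  # pragma: no cover
        return f"Framework({self.name})"


#: The 6 canonical frameworks, in fixed order.
FRAMEWORKS: tuple[Framework, ...] = (
    Framework(ConditionClass.OUTCOME, ActionClass.OWN_TRANSITION),   # DCU|wtl
    Framework(ConditionClass.OUTCOME, ActionClass.HAND),             # RPS|wtl
    Framework(ConditionClass.OWN_HAND, ActionClass.OWN_TRANSITION),  # DCU|rps
    Framework(ConditionClass.AI_HAND, ActionClass.OWN_TRANSITION),   # DCU|r_A p_A s_A
    Framework(ConditionClass.OUTCOME, ActionClass.AI_TRANSITION),    # D_A C_A U_A|wtl
    Framework(ConditionClass.AI_HAND, ActionClass.AI_TRANSITION),    # D_A C_A U_A|r_A p_A s_A
)


@dataclass(frozen=True)
class Rule:
    """One lag-1 rule: within a framework, a (condition, action) index pair in 0..2."""

    framework: Framework
    condition: int
    action: int

    @property
    def name(self) -> str:
        c = self.framework.condition_symbols()[self.condition]
        a = self.framework.action_symbols()[self.action]
        return f"{self.framework.name}:{a}|{c}"

    def __repr__(self) -> str:  # pragma: no cover
        return f"Rule({self.name})"


def enumerate_rules() -> list[Rule]:
    """All 54 rules in canonical order (frameworks, then condition, then action)."""
    return [
        Rule(fw, c, a)
        for fw in FRAMEWORKS
        for c in range(3)
        for a in range(3)
    ]


RULES: tuple[Rule, ...] = tuple(enumerate_rules())
RULE_NAMES: tuple[str, ...] = tuple(r.name for r in RULES)


# -- game -> (condition, action) sequences ---------------------------------

def condition_array(game: GameRecord, condition_class: ConditionClass) -> np.ndarray:
    """Condition codes for rounds 2..n, read from round k-1.  Length n-1."""
    if condition_class is ConditionClass.OWN_HAND:
        return game.hp[:-1]
    if condition_class is ConditionClass.AI_HAND:
        return game.ai[:-1]
    return game.out[:-1]


def action_array(game: GameRecord, action_class: ActionClass) -> np.ndarray:
    """Action codes for rounds 2..n.  Transitions are relative to round k-1 hands."""
    if action_class is ActionClass.HAND:
        return game.hp[1:]
    if action_class is ActionClass.OWN_TRANSITION:
        return transition_array(game.hp[:-1], game.hp[1:])
    return transition_array(game.ai[:-1], game.hp[1:])


def extract_observations(game: GameRecord, framework: Framework) -> pd.DataFrame:
    """(round, condition, action) observations for rounds 2..n under a framework.

    ``round`` is the 1-based round index k of the action; the condition was
    read from round k-1.  Codes are integers 0..2 in the framework's canonical
    symbol order.
    """
    if game.n_rounds < 2:
        raise ValueError("need at least 2 rounds to extract lag-1 observations")
    n = game.n_rounds
    return pd.DataFrame(
        {
            "round": np.arange(2, n + 1),
            "condition": condition_array(game, framework.condition_class),
            "action": action_array(game, framework.action_class),
        }
    )


def static_conditional_probs(game: GameRecord) -> pd.Series:
    """Whole-game p(action | condition) for all 54 rules, indexed by rule name.

    Computed as count(condition at k-1 followed by action at k) / count(condition);
    NaN where the condition never occurs in rounds 1..n-1.
    """
    if game.n_rounds < 2:
        raise ValueError("need at least 2 rounds")
    values = np.full(54, np.nan)
    i = 0
    for fw in FRAMEWORKS:
        cond = condition_array(game, fw.condition_class)
        act = action_array(game, fw.action_class)
        for c in range(3):
            mask = cond == c
            denom = int(mask.sum())
            for a in range(3):
                if denom > 0:
                    values[i] = float(np.sum(act[mask] == a)) / denom
                i += 1
    return pd.Series(values, index=list(RULE_NAMES), name="p(action|condition)")
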