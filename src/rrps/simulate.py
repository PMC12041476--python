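"""Simulated players and the game runner: the synthetic stand-in for a human cohort.

Three player families are provided:

* :class:`NMEPlayer` -- the Nash mixed equilibrium, choosing R/P/S uniformly
  at random each round; the only unexploitable strategy.
* :class:`ConstantPlayer` -- always the same hand (maximally exploitable).
* :class:`RuleSwitchingPlayer` -- plays from a lag-1 conditional probability
  matrix (a :class:`RuleSet`) and hops to a different ruleset at scheduled
  switch rounds.  Dominant matrix entries use probability A = 0.9 with the
  two alternatives at 0.05, and rows without serial dependence are
  equiprobable at 1/3; mean switch intervals of 11 or 14 rounds with uniform
  jitter emulate the simulated rule-switching conditions RS(n)vAI(i).

:func:`play_game` runs any player against the perceptron AI in a closed
loop, logging per-round AI confidence and (for switchers) ground-truth
switch rounds into the game metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .ai import PerceptronAI
from .game import GameRecord, Hand, apply_transition
from .rules import FRAMEWORKS, Framework, ActionClass, ConditionClass

__all__ = [
    "RuleSet",
    "SwitchSchedule",
    "make_rs_ruleset",
    "switch_schedule",
    "NMEPlayer",
    "ConstantPlayer",
    "RuleSwitchingPlayer",
    "play_game",
    "play_games",
    "bundled_ruleset_specs",
    "framework_by_name",
    "RS1_SPEC",
    "RS2_SPEC",
]

DEFAULT_A = 0.9
DEFAULT_MEAN_INTERVAL = 11
DEFAULT_JITTER = 3
DEFAULT_N_ROUNDS = 300


def framework_by_name(name: str) -> Framework:
    for fw in FRAMEWORKS:
        if fw.name == name:
            return fw
    raise ValueError(f"unknown framework {name!r}")


@dataclass(frozen=True)
class RuleSet:
    """A 3x3 lag-1 conditional probability matrix within one framework.

    ``matrix[c, a]`` = p(action a | condition c); every row sums to 1.
    """

    framework: Framework
    matrix: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", m)
        if m.shape != (3, 3):
            raise ValueError("ruleset matrix must be 3x3")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each condition row must sum to 1")

    def dominant_rules(self, min_p: float = 0.5) -> list[tuple[int, int]]:
        """(condition, action) pairs whose probability exceeds ``min_p``."""
        return [(c, a) for c in range(3) for a in range(3) if self.matrix[c, a] > min_p]


def make_rs_ruleset(
    pattern_spec: Sequence[int | None],
    A: float = DEFAULT_A,
    framework: Framework | str = "DCU|wtl",
    label: str = "",
) -> RuleSet:
    """Build a ruleset from a per-row pattern.

    ``pattern_spec`` gives, for each of the 3 conditions, either the index
    (0..2) of the dominant action -- its row becomes (A, (1-A)/2, (1-A)/2)
    permuted so A sits at that action -- or ``None`` for an equiprobable
    (1/3, 1/3, 1/3) row.  A must exceed 1/3 so the dominant entry dominates.
    """
    if not (1.0 / 3.0 < A <= 1.0):
        raise ValueError("dominant probability A must lie in (1/3, 1]")
    if len(pattern_spec) != 3:
        raise ValueError("pattern_spec must give one entry per condition row")
    if isinstance(framework, str):
        framework = framework_by_name(framework)
    rest = (1.0 - A) / 2.0
    m = np.empty((3, 3))
    for c, dom in enumerate(pattern_spec):
        if dom is None:
            m[c] = 1.0 / 3.0
        else:
            if dom not in (0, 1, 2):
                raise ValueError("dominant action index must be 0, 1 or 2 (or None)")
            m[c] = rest
            m[c, dom] = A
    return RuleSet(framework, m, label=label)


@dataclass(frozen=True)
class SwitchSchedule:
    """Rounds at which the active ruleset changes (the new ruleset takes effect
    at the switch round itself)."""

    switch_rounds: tuple[int, ...]
    mean_interval: float
    jitter: int

    def __post_init__(self) -> None:
        r = tuple(int(x) for x in self.switch_rounds)
        object.__setattr__(self, "switch_rounds", r)
        if any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError("switch rounds must be strictly increasing")


def switch_schedule(
    mean_interval: int = DEFAULT_MEAN_INTERVAL,
    jitter: int = DEFAULT_JITTER,
    n_rounds: int = DEFAULT_N_ROUNDS,
    rng: np.random.Generator | int | None = None,
) -> SwitchSchedule:
    """i.i.d. integer intervals uniform on [mean - jitter, mean + jitter], truncated at n_rounds."""
    if mean_interval <= 0:
        raise ValueError("mean_interval must be positive")
    if not (0 <= jitter < mean_interval):
        raise ValueError("jitter must satisfy 0 <= jitter < mean_interval")
    rng = np.random.default_rng(rng)
    rounds: list[int] = []
    t = 0
    while True:
        t += int(rng.integers(mean_interval - jitter, mean_interval + jitter + 1))
        if t >= n_rounds:
            break
        rounds.append(t)
    return SwitchSchedule(tuple(rounds), float(mean_interval), int(jitter))


class Player(Protocol):  # pragma: no cover - structural type only
    def reset(self) -> None: ...
    def move(self, k: int, hp: list[int], ai: list[int], out: list[int],
             rng: np.random.Generator) -> int: ...


class NMEPlayer:
    """Nash mixed equilibrium: each hand uniformly at random, every round."""

    kind = "nme"

    def reset(self) -> None:
        pass

    def move(self, k, hp, ai, out, rng) -> int:
        return int(rng.integers(3))


class ConstantPlayer:
    """Always plays the same hand."""

    kind = "constant"

    def __init__(self, hand: Hand | int = Hand.R):
        self.hand = int(hand)

    def reset(self) -> None:
        pass

    def move(self, k, hp, ai, out, rng) -> int:
        return self.hand


class RuleSwitchingPlayer:
    """Samples moves from an active lag-1 ruleset, hopping rulesets on schedule.

    At each scheduled switch round the active ruleset changes to a different
    member of ``rulesets``, chosen uniformly among the others; all three
    condition rows switch simultaneously.  On round 1 (no lag-1 condition)
    the move is uniform random.
    """

    kind = "rule_switching"

    def __init__(
        self,
        rulesets: Sequence[RuleSet],
        schedule: SwitchSchedule | None = None,
    ):
        if len(rulesets) < 1:
            raise ValueError("need at least one ruleset")
        if schedule is not None and schedule.switch_rounds and len(rulesets) < 2:
            raise ValueError("switching requires at least two rulesets")
        self.rulesets = list(rulesets)
        self.schedule = schedule or SwitchSchedule((), float("inf"), 0)
        self.reset()

    def reset(self) -> None:
        self.active = 0
        self._switch_iter = iter(self.schedule.switch_rounds)
        self._next_switch = next(self._switch_iter, None)
        self.active_history: list[int] = []

    def _maybe_switch(self, k: int, rng: np.random.Generator) -> None:
        while self._next_switch is not None and k >= self._next_switch:
            others = [i for i in range(len(self.rulesets)) if i != self.active]
            self.active = int(rng.choice(others))
            self._next_switch = next(self._switch_iter, None)

    def move(self, k, hp, ai, out, rng) -> int:
        self._maybe_switch(k, rng)
        self.active_history.append(self.active)
        rs = self.rulesets[self.active]
        if k == 1:
            return int(rng.integers(3))
        prev_hp, prev_ai, prev_out = hp[-1], ai[-1], out[-1]
        cc = rs.framework.condition_class
        cond = {ConditionClass.OWN_HAND: prev_hp,
                ConditionClass.AI_HAND: prev_ai,
                ConditionClass.OUTCOME: prev_out}[cc]
        a = int(rng.choice(3, p=rs.matrix[cond]))
        ac = rs.framework.action_class
        if ac is ActionClass.HAND:
            return a
        ref = prev_hp if ac is ActionClass.OWN_TRANSITION else prev_ai
        return int(apply_transition(ref, a))


# -- bundled rule-switching specifications ---------------------------------
# Each spec alternates between two rulesets in different frameworks; dominant
# rows use A and rows without serial dependence are equiprobable.

RS1_SPEC = (
    # win-upgrade / tie-copy with no serial dependence after losses
    ("DCU|wtl", (2, 1, None)),
    # beat the AI's rock, copy its scissors; no dependence after its paper
    ("D_A C_A U_A|r_A p_A s_A", (2, None, 1)),
)
RS2_SPEC = (
    # copy after own rock, upgrade after own scissors; paper row equiprobable
    ("DCU|rps", (1, None, 2)),
    # downgrade the AI's hand after wins, upgrade it after losses
    ("D_A C_A U_A|wtl", (0, None, 2)),
)


def bundled_ruleset_specs(name: str, A: float = DEFAULT_A) -> list[RuleSet]:
    """The two bundled rule-switching specifications, ``"rs1"`` and ``"rs2"``."""
    spec = {"rs1": RS1_SPEC, "rs2": RS2_SPEC}.get(name.lower())
    if spec is None:
        raise ValueError(f"unknown bundled spec {name!r}; expected 'rs1' or 'rs2'")
    return [
        make_rs_ruleset(pattern, A=A, framework=fw, label=f"{name}:rule{i + 1}")
        for i, (fw, pattern) in enumerate(spec)
    ]


# -- the closed game loop --------------------------------------------------

def _synth_response_times(n: int, rng: np.random.Generator) -> np.ndarray:
    """Plausible self-paced response times (ms): lognormal, median ~850 ms."""
    return np.exp(rng.normal(np.log(850.0), 0.35, size=n)) * 1.0


def play_game(
    player,
    ai: PerceptronAI | None = None,
    n_rounds: int = DEFAULT_N_ROUNDS,
    rng: np.random.Generator | int | None = None,
    player_id: str = "sim",
    opponent: "Player | None" = None,
) -> GameRecord:
    """Run a player against the AI (or, if ``opponent`` is given, another player).

    Both sides commit a hand each round from the history through round k-1;
    the outcome is recorded and the AI updated online.  The returned
    :class:`GameRecord` carries per-round AI confidence and, for
    rule-switching players, the ground-truth switch rounds in its metadata.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    rng = np.random.default_rng(rng)
    if ai is None and opponent is None:
        ai = PerceptronAI(rng_seed=int(rng.integers(2**31)))
    player.reset()
    if opponent is not None:
        opponent.reset()

    hp_hist: list[int] = []
    ai_hist: list[int] = []
    out_hist: list[int] = []
    confidence = np.empty((n_rounds, 3))

    for k in range(1, n_rounds + 1):
        if ai is not None:
            confidence[k - 1] = ai.confidence()
            ai_move = int(ai.choose_move())
        else:
            # opponent-vs-player game (e.g. rule switcher vs NME): the
            # "AI side" is just the opponent player; confidence is uniform.
            # Outcomes are flipped to the opponent's perspective (W<->L).
            confidence[k - 1] = 1.0 / 3.0
            ai_move = opponent.move(k, ai_hist, hp_hist, [2 - o for o in out_hist], rng)
        hp_move = player.move(k, hp_hist, ai_hist, out_hist, rng)
        o = (hp_move - ai_move) % 3  # 0 tie ... mapped below
        out_code = {0: 1, 1: 0, 2: 2}[o]  # W=0, T=1, L=2
        if ai is not None:
            ai.update(hp_move)
            ai.record_own_move(ai_move)
        hp_hist.append(hp_move)
        ai_hist.append(ai_move)
        out_hist.append(out_code)

    rt = _synth_response_times(n_rounds, rng)
    wall = np.cumsum(rt) / 1000.0 + 0.3 * np.arange(1, n_rounds + 1)
    metadata: dict = {
        "player_type": getattr(player, "kind", type(player).__name__),
        "ai_confidence": confidence,
        "opponent": "perceptron_ai" if ai is not None else getattr(opponent, "kind", "player"),
    }
    if ai is not None:
        metadata["ai_learning_rate"] = ai.learning_rate
        metadata["ai_seed"] = ai.rng_seed
    if isinstance(player, RuleSwitchingPlayer):
        metadata["true_switch_rounds"] = list(player.schedule.switch_rounds)
        metadata["ruleset_labels"] = [rs.label for rs in player.rulesets]
    return GameRecord(player_id=player_id, hp=np.array(hp_hist), ai=np.array(ai_hist),
                      rt_ms=rt, wall_s=wall, metadata=metadata)


def make_player(
    kind: str,
    rng: np.random.Generator,
    mean_interval: int = DEFAULT_MEAN_INTERVAL,
    jitter: int = DEFAULT_JITTER,
    n_rounds: int = DEFAULT_N_ROUNDS,
    A: float = DEFAULT_A,
):
    """Construct a named player (``nme``, ``constant``, ``rs1``, ``rs2``)."""
    kind = kind.lower()
    if kind == "nme":
        return NMEPlayer()
    if kind == "constant":
        return ConstantPlayer()
    if kind in ("rs1", "rs2"):
        sched = switch_schedule(mean_interval, jitter, n_rounds, rng)
        return RuleSwitchingPlayer(bundled_ruleset_specs(kind, A=A), sched)
    raise ValueError(f"unknown player kind {kind!r}")


def play_games(
    kind: str,
    n_games: int,
    n_rounds: int = DEFAULT_N_ROUNDS,
    seed: int | None = None,
    mean_interval: int = DEFAULT_MEAN_INTERVAL,
    jitter: int = DEFAULT_JITTER,
    learning_rate: float = 0.1,
    A: float = DEFAULT_A,
    vs_nme: bool = False,
) -> list[GameRecord]:
    """Simulate a batch of independent games of one player kind vs the AI.

    With ``vs_nme=True`` the opponent is an NME player instead of the
    learning AI (the control condition in which rule switches confer no
    advantage).
    """
    root = np.random.default_rng(seed)
    games = []
    for g in range(n_games):
        rng = np.random.default_rng(root.integers(2**31))
        player = make_player(kind, rng, mean_interval, jitter, n_rounds, A)
        if vs_nme:
            game = play_game(player, ai=None, opponent=NMEPlayer(),
                             n_rounds=n_rounds, rng=rng,
                             player_id=f"{kind}_vs_nme_{g:04d}")
        else:
            ai = PerceptronAI(learning_rate=learning_rate,
                              rng_seed=int(root.integers(2**31)))
            game = play_game(player, ai=ai, n_rounds=n_rounds, rng=rng,
                             player_id=f"{kind}_{g:04d}")
        games.append(game)
    return games
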