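"""Dynamic conditional-probability traces and permutation-null repertoire detection.

For each lag-1 rule we estimate a *dynamic* conditional response probability
p(action | condition)(round): sliding over each run of B consecutive
occurrences of the rule's condition, the fraction of those B occurrences
followed by the rule's action is anchored at the round of the window's first
occurrence, and linearly interpolated between anchors (the rule is assumed to
persist in mind between conditioning events).  With the default B = 3 the raw
window estimates can only take values {0, 1/3, 2/3, 1}.

The rule shuffle score (RSS) is the number of rounds the trace spends
strictly above a threshold (default 0.8).  Its significance is assessed
against a null built by permuting the order of whole rounds -- move content
intact, temporal structure destroyed -- and a rule is deemed *in repertoire*
when its real RSS reaches the 98th percentile of that null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .game import GameRecord
from .rules import FRAMEWORKS, RULES, Rule, condition_array, action_array

__all__ = [
    "ProbTrace",
    "RepertoireResult",
    "prob_trace",
    "all_traces",
    "time_above_threshold",
    "shuffle_null",
    "detect_repertoire",
]

DEFAULT_B = 3
DEFAULT_THRESHOLD = 0.8
DEFAULT_PERCENTILE_CUT = 98.0
DEFAULT_N_SHUFFLES = 200


@dataclass
class ProbTrace:
    """A per-round dynamic probability trace for one rule.

    ``values`` has length n (rounds 1..n); all-NaN when the game contains
    fewer than B occurrences of the rule's condition.  ``anchor_rounds`` are
    the conditioning-event rounds where raw window estimates attach, and
    ``anchor_values`` the raw #matching / B estimates.
    """

    rule: Rule
    values: np.ndarray
    B: int
    anchor_rounds: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    anchor_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: 1-based rounds of *all* occurrences of the rule's condition (the
    #: conditioning rounds); the switch detector re-anchors windows causally
    #: from these.
    occurrence_rounds: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def defined(self) -> bool:
        return bool(len(self.anchor_rounds))


@dataclass
class RepertoireResult:
    """Per-rule repertoire verdict: RSS against its round-shuffle null."""

    rule: Rule
    rss: int
    null_rss: np.ndarray
    percentile: float  # NaN when the rule's condition occurred < B times
    in_repertoire: bool
    threshold: float = DEFAULT_THRESHOLD
    percentile_cut: float = DEFAULT_PERCENTILE_CUT


def _window_estimates(
    cond: np.ndarray, act: np.ndarray, c: int, a: int, B: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Anchor rounds, raw sliding-window estimates and all occurrence rounds.

    ``cond``/``act`` are the length n-1 lag-1 observation arrays; index i
    corresponds to the action at round i+2 conditioned on round i+1.  The
    m-th window covers conditioning events m..m+B-1 and anchors at the round
    of event m (i.e. the conditioning round, not the action round).
    """
    occ = np.flatnonzero(cond == c)
    occ_rounds = (occ + 1).astype(np.int64)
    if len(occ) < B:
        return np.empty(0, dtype=np.int64), np.empty(0), occ_rounds
    match = (act[occ] == a).astype(np.float64)
    s = np.concatenate(([0.0], np.cumsum(match)))
    ests = (s[B:] - s[:-B]) / B
    anchors = occ[: len(ests)] + 1  # conditioning round of the window's first event
    return anchors.astype(np.int64), ests, occ_rounds


def _interp_trace(anchors: np.ndarray, ests: np.ndarray, n: int) -> np.ndarray:
    """Linear interpolation between anchors; held at the nearest estimate at the edges."""
    if len(anchors) == 0:
        return np.full(n, np.nan)
    return np.interp(np.arange(1, n + 1), anchors, ests)


def prob_trace(game: GameRecord, rule: Rule, B: int = DEFAULT_B) -> ProbTrace:
    """Sliding-window dynamic p(action|condition)(round) trace for one rule."""
    if B < 1:
        raise ValueError("window size B must be >= 1")
    cond = condition_array(game, rule.framework.condition_class)
    act = action_array(game, rule.framework.action_class)
    anchors, ests, occ_rounds = _window_estimates(cond, act, rule.condition, rule.action, B)
    return ProbTrace(
        rule=rule,
        values=_interp_trace(anchors, ests, game.n_rounds),
        B=B,
        anchor_rounds=anchors,
        anchor_values=ests,
        occurrence_rounds=occ_rounds,
    )


def all_traces(game: GameRecord, B: int = DEFAULT_B) -> list[ProbTrace]:
    """Traces for all 54 rules in canonical order (shared per-framework encoding)."""
    n = game.n_rounds
    traces: list[ProbTrace] = []
    for fw in FRAMEWORKS:
        cond = condition_array(game, fw.condition_class)
        act = action_array(game, fw.action_class)
        for c in range(3):
            for a in range(3):
                anchors, ests, occ_rounds = _window_estimates(cond, act, c, a, B)
                rule = RULES[len(traces)]
                traces.append(
                    ProbTrace(rule, _interp_trace(anchors, ests, n), B,
                              anchors, ests, occ_rounds)
                )
    return traces


def time_above_threshold(trace: ProbTrace, thr: float = DEFAULT_THRESHOLD) -> int:
    """Number of rounds whose (defined) trace value is strictly above ``thr``."""
    v = trace.values
    return int(np.sum(v[~np.isnan(v)] > thr))


def _tat_from_arrays(
    cond: np.ndarray, act: np.ndarray, c: int, a: int, B: int, thr: float, n: int
) -> Optional[int]:
    anchors, ests, _ = _window_estimates(cond, act, c, a, B)
    if len(anchors) == 0:
        return None
    return int(np.sum(_interp_trace(anchors, ests, n) > thr))


def shuffle_null(
    game: GameRecord,
    rule: Rule,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    rng: np.random.Generator | int | None = None,
    B: int = DEFAULT_B,
    thr: float = DEFAULT_THRESHOLD,
) -> np.ndarray:
    """Null RSS distribution for one rule: whole-round permutations of the game.

    Each draw permutes the order of the rounds (keeping each round's
    (player hand, AI hand, outcome) intact), re-extracts the lag-1
    observations, recomputes the trace and counts rounds above threshold.
    Draws where the permuted game yields an undefined trace contribute 0.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(rng)
    n = game.n_rounds
    out = np.zeros(n_shuffles, dtype=np.int64)
    for i in range(n_shuffles):
        g = game.permuted(rng.permutation(n))
        cond = condition_array(g, rule.framework.condition_class)
        act = action_array(g, rule.framework.action_class)
        tat = _tat_from_arrays(cond, act, rule.condition, rule.action, B, thr, n)
        out[i] = 0 if tat is None else tat
    return out


def _percentile_of(real: int, null: np.ndarray) -> float:
    """Strict percentile of score: fraction of null values strictly below, x100.

    Ties do not count as "below", so a statistic that merely equals the whole
    null distribution (common with the integer-valued RSS, e.g. an all-zero
    null) sits at the 0th percentile, keeping the 98th-percentile call at its
    nominal ~2% false-positive rate.
    """
    return 100.0 * float(np.sum(null < real)) / len(null)


def detect_repertoire(
    game: GameRecord,
    B: int = DEFAULT_B,
    thr: float = DEFAULT_THRESHOLD,
    percentile_cut: float = DEFAULT_PERCENTILE_CUT,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    rng: np.random.Generator | int | None = None,
) -> list[RepertoireResult]:
    """Classify each of the 54 rules as in- or out-of-repertoire for one game.

    One set of ``n_shuffles`` whole-round permutations is drawn per game and
    shared across all rules (each rule's percentile only involves its own
    marginal null, so sharing permutations leaves the per-rule test
    unchanged while avoiding a 54-fold recomputation).

    Rules whose condition occurs fewer than B times have no defined trace and
    are returned as not-in-repertoire with NaN percentile and RSS 0.
    """
    rng = np.random.default_rng(rng)
    n = game.n_rounds

    # Real statistics.
    real_tat: list[Optional[int]] = []
    for fw in FRAMEWORKS:
        cond = condition_array(game, fw.condition_class)
        act = action_array(game, fw.action_class)
        for c in range(3):
            for a in range(3):
                real_tat.append(_tat_from_arrays(cond, act, c, a, B, thr, n))

    # Shared permutation null.
    null = np.zeros((n_shuffles, 54), dtype=np.int64)
    for i in range(n_shuffles):
        g = game.permuted(rng.permutation(n))
        j = 0
        for fw in FRAMEWORKS:
            cond = condition_array(g, fw.condition_class)
            act = action_array(g, fw.action_class)
            for c in range(3):
                occ = np.flatnonzero(cond == c)
                if len(occ) < B:
                    j += 3
                    continue
                sub = act[occ]
                for a in range(3):
                    match = (sub == a).astype(np.float64)
                    s = np.concatenate(([0.0], np.cumsum(match)))
                    ests = (s[B:] - s[:-B]) / B
                    anchors = occ[: len(ests)] + 1
                    null[i, j] = int(
                        np.sum(np.interp(np.arange(1, n + 1), anchors, ests) > thr)
                    )
                    j += 1

    results: list[RepertoireResult] = []
    for j, rule in enumerate(RULES):
        if real_tat[j] is None:
            results.append(
                RepertoireResult(rule, 0, null[:, j].copy(), float("nan"), False, thr, percentile_cut)
            )
            continue
        pct = _percentile_of(real_tat[j], null[:, j])
        results.append(
            RepertoireResult(
                rule, int(real_tat[j]), null[:, j].copy(), pct, pct >= percentile_cut, thr, percentile_cut
            )
        )
    return results


def repertoire_percentiles(results: Sequence[RepertoireResult]) -> np.ndarray:
    """The 54 RSS percentiles in canonical rule order (NaN where undefined)."""
    return np.array([r.percentile for r in results])
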