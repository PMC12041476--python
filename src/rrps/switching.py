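"""Rule-change detection and the rule-switch triggered net-win curve (RSTW).

A switch of the active heuristic shows up as a rapid swing of an
in-repertoire rule's dynamic probability trace from near 0 to near 1 or
back.  Detection must be causal: a ruleset change is invisible until the
affected conditioning events recur and the player's following actions reveal
the new contingency.  The detector therefore re-anchors the sliding-window
estimates at the round where each window's evidence is complete -- the round
of the action following the window's final conditioning event -- and scans
the re-anchored sequence for full swings: monotone excursions from a
flanking extremum at or below ``low_level`` to one at or above
``high_level`` (or vice versa) completing within ``max_swing_span`` rounds.
An event is stamped at the swing's completion, the first round at which the
estimate sits at the far level.  Candidate events from different rules are
merged when closer than ``merge_window`` rounds (a single underlying ruleset
change moves several conditional rows at once) keeping the earliest.

The payoff of switching is measured by the rule-switch triggered net wins

    RSTW(lag) = (#wins at lag - #losses at lag) / (#wins at lag + #losses at lag),

outcome segments stacked around every detected event; ties are excluded
from both numerator and denominator.  Against the constantly-learning AI the
curve rises near the detected switch -- the AI's model of the player has
just gone obsolete -- whereas against a non-learning opponent it stays flat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .game import GameRecord, Outcome
from .repertoire import ProbTrace, RepertoireResult

__all__ = [
    "SwitchEvents",
    "RSTWCurve",
    "detect_switches",
    "switch_events_for_game",
    "rstw",
    "detection_lag_histogram",
]

DEFAULT_LOW = 0.2
DEFAULT_HIGH = 0.8
DEFAULT_MERGE_WINDOW = 3
DEFAULT_MAX_SWING_SPAN = 9
DEFAULT_MAX_LAG = 15


@dataclass
class SwitchEvents:
    """Detected rule-change rounds for one game, with per-event source rules."""

    game_id: str
    detected_rounds: tuple[int, ...]
    source_rules: tuple[tuple[str, ...], ...]  # rule names merged into each event

    def __len__(self) -> int:
        return len(self.detected_rounds)


@dataclass
class RSTWCurve:
    """Net-win fraction at each signed lag around detected switch events."""

    lags: np.ndarray
    values: np.ndarray       # (#wins - #losses) / (#wins + #losses); NaN if none
    wins: np.ndarray
    losses: np.ndarray
    n_events: int

    @property
    def event_counts(self) -> np.ndarray:
        return self.wins + self.losses


def _causal_anchors(trace: ProbTrace) -> tuple[np.ndarray, np.ndarray]:
    """Re-anchor the window estimates causally.

    The m-th window covers conditioning events m..m+B-1; its estimate is
    fully determined at the round of the action following event m+B-1, i.e.
    one round after that conditioning round.  Returns (rounds, estimates).
    """
    occ = trace.occurrence_rounds
    ests = trace.anchor_values
    if len(ests) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    return occ[trace.B - 1:] + 1, ests


def _swing_candidates(
    rounds: np.ndarray,
    values: np.ndarray,
    low: float,
    high: float,
    max_span: int,
) -> list[int]:
    """Completion rounds of full swings across [low, high] in an anchored sequence.

    Runs of equal values are compressed toward the excursion, so flat
    plateaus at the extremes do not inflate the swing span; the span is
    measured from the last anchor of the starting extremum's run to the
    first anchor of the arriving run, where the event is stamped.
    """
    r = np.asarray(rounds)
    v = np.asarray(values)
    if len(r) < 2:
        return []
    keep_first = np.concatenate(([True], v[1:] != v[:-1]))
    run_id = np.cumsum(keep_first) - 1
    n_runs = run_id[-1] + 1
    if n_runs < 2:
        return []
    first_idx = np.searchsorted(run_id, np.arange(n_runs), side="left")
    last_idx = np.searchsorted(run_id, np.arange(n_runs), side="right") - 1
    rv = v[first_idx]  # value per run

    events: list[int] = []
    dirs = np.sign(np.diff(rv))  # +1 rising, -1 falling between runs
    seg_start = 0
    for i in range(1, len(dirs) + 1):
        if i == len(dirs) or dirs[i] != dirs[seg_start]:
            v0, v1 = rv[seg_start], rv[i]
            r0 = r[last_idx[seg_start]]   # flanking extremum: nearest anchor
            r1 = r[first_idx[i]]          # completion: first anchor at far level
            full_swing = (v0 <= low and v1 >= high) or (v0 >= high and v1 <= low)
            if full_swing and (r1 - r0) <= max_span:
                events.append(int(r1))
            seg_start = i
    return events


def detect_switches(
    traces: Sequence[ProbTrace],
    results: Sequence[RepertoireResult] | None = None,
    game_id: str = "",
    low_level: float = DEFAULT_LOW,
    high_level: float = DEFAULT_HIGH,
    merge_window: int = DEFAULT_MERGE_WINDOW,
    max_swing_span: int = DEFAULT_MAX_SWING_SPAN,
) -> SwitchEvents:
    """Detect rule-change rounds from in-repertoire probability traces.

    ``traces`` should already be restricted to in-repertoire rules, or pass
    the matching ``results`` (canonical order) and the restriction is applied
    here.  With no in-repertoire rules the event list is empty.
    """
    if results is not None:
        traces = [t for t, res in zip(traces, results) if res.in_repertoire]
    cand: list[tuple[int, str]] = []
    for t in traces:
        rounds, values = _causal_anchors(t)
        for e in _swing_candidates(rounds, values, low_level, high_level, max_swing_span):
            cand.append((e, t.rule.name))
    cand.sort()
    kept_rounds: list[int] = []
    kept_rules: list[list[str]] = []
    for e, rule_name in cand:
        if kept_rounds and e - kept_rounds[-1] < merge_window:
            kept_rules[-1].append(rule_name)
        else:
            kept_rounds.append(e)
            kept_rules.append([rule_name])
    return SwitchEvents(
        game_id=game_id,
        detected_rounds=tuple(kept_rounds),
        source_rules=tuple(tuple(rs) for rs in kept_rules),
    )


def switch_events_for_game(
    game: GameRecord,
    B: int = 3,
    thr: float = 0.8,
    percentile_cut: float = 98.0,
    n_shuffles: int = 200,
    rng: np.random.Generator | int | None = None,
    **detector_kwargs,
) -> SwitchEvents:
    """Convenience: repertoire detection then switch detection for one game."""
    from .repertoire import all_traces, detect_repertoire

    results = detect_repertoire(game, B=B, thr=thr, percentile_cut=percentile_cut,
                                n_shuffles=n_shuffles, rng=rng)
    traces = all_traces(game, B=B)
    return detect_switches(traces, results, game_id=game.player_id, **detector_kwargs)


def rstw(
    games: Sequence[GameRecord],
    events: Sequence[SwitchEvents],
    max_lag: int = DEFAULT_MAX_LAG,
) -> RSTWCurve:
    """Stack outcome segments around every detected event and net the wins.

    At each lag in [-max_lag, +max_lag], value = (#wins - #losses) /
    (#wins + #losses) over all events of all games; ties contribute to
    neither count, and lags with no win/loss events are NaN.
    """
    lags = np.arange(-max_lag, max_lag + 1)
    wins = np.zeros(len(lags), dtype=np.int64)
    losses = np.zeros(len(lags), dtype=np.int64)
    n_events = 0
    for game, ev in zip(games, events):
        n = game.n_rounds
        is_w = game.out == Outcome.W
        is_l = game.out == Outcome.L
        for e in ev.detected_rounds:
            n_events += 1
            ks = e + lags
            ok = (ks >= 1) & (ks <= n)
            wins[ok] += is_w[ks[ok] - 1]
            losses[ok] += is_l[ks[ok] - 1]
    denom = wins + losses
    values = np.where(denom > 0, (wins - losses) / np.maximum(denom, 1), np.nan)
    return RSTWCurve(lags=lags, values=values, wins=wins, losses=losses, n_events=n_events)


def detection_lag_histogram(
    true_rounds: Sequence[int],
    detected_rounds: Sequence[int],
    max_lag: int = DEFAULT_MAX_LAG,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of detected events at each signed lag from every true change.

    Returns ``(lags, counts)`` with lags in [-max_lag, +max_lag]; each
    (true, detected) pair within range contributes one count at
    ``detected - true``.
    """
    lags = np.arange(-max_lag, max_lag + 1)
    counts = np.zeros(len(lags), dtype=np.int64)
    det = np.asarray(sorted(detected_rounds), dtype=np.int64)
    for t in true_rounds:
        d = det[(det >= t - max_lag) & (det <= t + max_lag)]
        for x in d:
            counts[x - t + max_lag] += 1
    return lags, counts
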