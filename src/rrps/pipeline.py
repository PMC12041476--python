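"""Batch pipeline helpers: simulate a cohort, detect repertoires and switches.

These functions tie the stages together for the simulation study conditions
(rule-switching players RS(n)vAI(i) and NME players vs the learning AI) and
compute the summary quantities of interest: the fraction of games with at
least one detected rule change, events per game, the ground-truth-triggered
detection-lag histogram, and the RSTW curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .game import GameRecord
from .repertoire import all_traces, detect_repertoire
from .switching import (SwitchEvents, detect_switches, detection_lag_histogram,
                        rstw, RSTWCurve)
from .simulate import play_games

__all__ = ["BatchDetection", "detect_batch", "simulate_and_detect", "peak_lag"]


@dataclass
class BatchDetection:
    games: list[GameRecord]
    events: list[SwitchEvents]

    @property
    def n_games(self) -> int:
        return len(self.games)

    @property
    def frac_with_events(self) -> float:
        """Fraction of games with at least one detected rule change."""
        return float(np.mean([len(e) > 0 for e in self.events]))

    @property
    def mean_events_among_detected(self) -> float:
        """Mean events per game among games with at least one detection."""
        counts = [len(e) for e in self.events if len(e) > 0]
        return float(np.mean(counts)) if counts else float("nan")

    def rstw(self, max_lag: int = 15) -> RSTWCurve:
        return rstw(self.games, self.events, max_lag=max_lag)

    def lag_histogram(self, max_lag: int = 15) -> tuple[np.ndarray, np.ndarray]:
        """Pooled histogram of detected-event lags from ground-truth switches."""
        lags = np.arange(-max_lag, max_lag + 1)
        total = np.zeros(len(lags), dtype=np.int64)
        for g, ev in zip(self.games, self.events):
            true_rounds = g.metadata.get("true_switch_rounds")
            if not true_rounds:
                continue
            _, counts = detection_lag_histogram(true_rounds, ev.detected_rounds, max_lag)
            total += counts
        return lags, total


def detect_batch(
    games: list[GameRecord],
    B: int = 3,
    thr: float = 0.8,
    percentile_cut: float = 98.0,
    n_shuffles: int = 200,
    seed: int | None = None,
    low_level: float = 0.2,
    high_level: float = 0.8,
    merge_window: int = 3,
    max_swing_span: int = 9,
) -> BatchDetection:
    """Run repertoire + switch detection over a batch of games."""
    root = np.random.default_rng(seed)
    events = []
    for g in games:
        results = detect_repertoire(g, B=B, thr=thr, percentile_cut=percentile_cut,
                                    n_shuffles=n_shuffles,
                                    rng=int(root.integers(2**31)))
        traces = all_traces(g, B=B)
        events.append(detect_switches(traces, results, game_id=g.player_id,
                                      low_level=low_level, high_level=high_level,
                                      merge_window=merge_window,
                                      max_swing_span=max_swing_span))
    return BatchDetection(games=games, events=events)


def simulate_and_detect(
    kind: str,
    n_games: int,
    seed: int,
    n_rounds: int = 300,
    mean_interval: int = 11,
    n_shuffles: int = 200,
    vs_nme: bool = False,
    **detect_kwargs,
) -> BatchDetection:
    """Simulate a cohort of one player kind and run the detection pipeline on it."""
    games = play_games(kind, n_games, n_rounds=n_rounds, seed=seed,
                       mean_interval=mean_interval, vs_nme=vs_nme)
    return detect_batch(games, n_shuffles=n_shuffles, seed=seed + 1, **detect_kwargs)


def peak_lag(lags: np.ndarray, counts: np.ndarray) -> int:
    """Lag of the histogram mode (smallest lag on ties)."""
    return int(lags[int(np.argmax(counts))])
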