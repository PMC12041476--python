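"""Game-record serialization, engagement quality control, and pipeline config.

Games are stored as a long-format CSV -- one row per round with columns
``game_id, round, hp_hand, ai_hand, outcome, rt_ms, wall_time_s`` -- plus a
JSON sidecar (``<stem>.meta.json``) holding per-game metadata: player type,
seeds, AI parameters, ground-truth switch rounds and the per-round AI
confidence.  Reading validates hand symbols, round-index contiguity and the
consistency of the recorded outcome with the hands, reporting offending
line numbers.

Engagement QC mirrors the assay's screening of self-paced online play: a
game fails if the mean response time is under 600 ms (suspiciously fast for
a deliberate choice), if the player repeats the same hand more than 15
times in a row, or if more than 10 inter-round gaps exceed one minute
(heuristic play is history-dependent, so long pauses corrupt the lag-1
structure).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .game import GameRecord, Hand, Outcome, outcome

__all__ = ["QCReport", "qc_engagement", "write_games", "read_games",
           "PipelineConfig", "load_config"]

_HAND_SYMS = {0: "R", 1: "P", 2: "S"}
_OUT_SYMS = {0: "w", 1: "t", 2: "l"}

MEAN_RT_FLOOR_MS = 600.0
MAX_REPEAT_STREAK = 15
MAX_LONG_PAUSES = 10
LONG_PAUSE_S = 60.0


@dataclass
class QCReport:
    """Engagement verdict for one game; ``pass_`` iff ``reasons`` is empty."""

    player_id: str
    pass_: bool
    reasons: list[str]
    metrics: dict

    def __post_init__(self) -> None:
        assert self.pass_ == (len(self.reasons) == 0)


def _max_streak(hands: np.ndarray) -> int:
    best = run = 1
    for a, b in zip(hands[:-1], hands[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def qc_engagement(game: GameRecord) -> QCReport:
    """Apply the three engagement filters to one game.

    Absent wall times skip the long-pause check (noted in the metrics).
    """
    if game.n_rounds == 0:
        raise ValueError("empty game")
    reasons: list[str] = []
    mean_rt = float(np.mean(game.rt_ms))
    if mean_rt < MEAN_RT_FLOOR_MS:
        reasons.append("fast_responder")
    streak = _max_streak(game.hp)
    if streak > MAX_REPEAT_STREAK:
        reasons.append("repeat_streak")
    metrics = {"mean_rt_ms": mean_rt, "max_repeat_streak": streak}
    if game.wall_s is None:
        metrics["long_pauses"] = None
        metrics["long_pause_check_skipped"] = True
    else:
        gaps = int(np.sum(np.diff(game.wall_s) > LONG_PAUSE_S))
        metrics["long_pauses"] = gaps
        if gaps > MAX_LONG_PAUSES:
            reasons.append("long_pauses")
    return QCReport(game.player_id, not reasons, reasons, metrics)


# -- serialization ---------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_games(games: Sequence[GameRecord], path: str | Path) -> Path:
    """Write games to a long-format CSV plus a JSON metadata sidecar.

    Returns the sidecar path.  ``game_id`` is the record's ``player_id``,
    which must be unique within the batch.
    """
    path = Path(path)
    ids = [g.player_id for g in games]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate game ids in batch")
    frames = []
    meta = {}
    for g in games:
        n = g.n_rounds
        frames.append(pd.DataFrame({
            "game_id": g.player_id,
            "round": np.arange(1, n + 1),
            "hp_hand": [_HAND_SYMS[int(h)] for h in g.hp],
            "ai_hand": [_HAND_SYMS[int(h)] for h in g.ai],
            "outcome": [_OUT_SYMS[int(o)] for o in g.out],
            "rt_ms": g.rt_ms,
            "wall_time_s": g.wall_s if g.wall_s is not None else np.full(n, np.nan),
        }))
        meta[g.player_id] = _jsonable(g.metadata)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")
    mpath = _meta_path(path)
    mpath.write_text(json.dumps(meta))
    return mpath


class GameParseError(ValueError):
    pass


def read_games(path: str | Path) -> list[GameRecord]:
    """Read games written by :func:`write_games`, validating as it goes.

    Raises :class:`GameParseError` naming the first offending CSV line for
    invalid hand/outcome symbols, duplicate or gapped round indices, or an
    outcome column inconsistent with the hands.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"game_id": str})
    required = {"game_id", "round", "hp_hand", "ai_hand", "outcome", "rt_ms"}
    missing = required - set(df.columns)
    if missing:
        raise GameParseError(f"{path}: missing columns {sorted(missing)}")
    sym_to_hand = {"R": 0, "P": 1, "S": 2}
    sym_to_out = {"w": 0, "t": 1, "l": 2}
    # CSV line numbers: header is line 1
    df = df.assign(_line=df.index + 2)

    mpath = _meta_path(path)
    meta_all = json.loads(mpath.read_text()) if mpath.exists() else {}

    games: list[GameRecord] = []
    for gid, sub in df.groupby("game_id", sort=False):
        sub = sub.sort_values("round")
        rounds = sub["round"].to_numpy()
        if len(np.unique(rounds)) != len(rounds):
            dup = sub[sub["round"].duplicated()].iloc[0]
            raise GameParseError(f"{path} line {dup['_line']}: duplicate round {dup['round']} in game {gid}")
        if rounds[0] != 1 or np.any(np.diff(rounds) != 1):
            raise GameParseError(f"{path}: game {gid} round indices are not contiguous 1..n")
        for col, table, kind in (("hp_hand", sym_to_hand, "hand"),
                                 ("ai_hand", sym_to_hand, "hand"),
                                 ("outcome", sym_to_out, "outcome")):
            bad = sub[~sub[col].astype(str).str.strip().isin(table)]
            if len(bad):
                row = bad.iloc[0]
                raise GameParseError(
                    f"{path} line {row['_line']}: invalid {kind} symbol {row[col]!r}")
        hp = sub["hp_hand"].str.strip().map(sym_to_hand).to_numpy(np.int8)
        ai = sub["ai_hand"].str.strip().map(sym_to_hand).to_numpy(np.int8)
        out = sub["outcome"].str.strip().map(sym_to_out).to_numpy(np.int8)
        expect = np.array([int(outcome(a, b)) for a, b in zip(hp, ai)], dtype=np.int8)
        if np.any(out != expect):
            row = sub.iloc[int(np.argmax(out != expect))]
            raise GameParseError(
                f"{path} line {row['_line']}: outcome {row['outcome']!r} inconsistent with hands "
                f"{row['hp_hand']!r} vs {row['ai_hand']!r}")
        wall = sub["wall_time_s"].to_numpy(float) if "wall_time_s" in sub else None
        if wall is not None and np.isnan(wall).all():
            wall = None
        metadata = meta_all.get(str(gid), {})
        if "ai_confidence" in metadata:
            metadata["ai_confidence"] = np.asarray(metadata["ai_confidence"], dtype=float)
        games.append(GameRecord(player_id=str(gid), hp=hp, ai=ai,
                                rt_ms=sub["rt_ms"].to_numpy(float),
                                wall_s=wall, metadata=metadata))
    return games


# -- configuration ---------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunable defaults of the pipeline, overridable from YAML."""

    B: int = 3
    threshold: float = 0.8
    percentile_cut: float = 98.0
    n_shuffles: int = 200
    learning_rate: float = 0.1
    n_rounds: int = 300
    mean_interval: int = 11
    jitter: int = 3
    low_level: float = 0.2
    high_level: float = 0.8
    merge_window: int = 3
    max_swing_span: int = 9
    max_lag: int = 15
    dominant_p: float = 0.9
    outer_folds: int = 4
    inner_folds: int = 3
    n_id_shuffles: int = 100

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig`, applying YAML overrides if a path is given."""
    cfg = PipelineConfig()
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(asdict(cfg))
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k, v in data.items():
            setattr(cfg, k, v)
    return cfg
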