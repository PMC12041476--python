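"""Shared fixtures: small hand-built games and simulated batches."""

from __future__ import annotations

import numpy as np
import pytest

from rrps.game import GameRecord, Hand, Outcome

H = {"R": 0, "P": 1, "S": 2}


def game_from_hands(hp_syms: str, ai_syms: str, player_id: str = "toy",
                    rt_ms=None, wall_s=None, metadata=None) -> GameRecord:
    """Build a GameRecord from strings of hand symbols, e.g. 'RPS', 'SSR'."""
    hp = np.array([H[c] for c in hp_syms], dtype=np.int8)
    ai = np.array([H[c] for c in ai_syms], dtype=np.int8)
    n = len(hp)
    return GameRecord(
        player_id=player_id, hp=hp, ai=ai,
        rt_ms=np.full(n, 800.0) if rt_ms is None else np.asarray(rt_ms, float),
        wall_s=wall_s, metadata=metadata or {},
    )


def game_from_outcomes(outs: str, player_id: str = "toy") -> GameRecord:
    """A game realizing the given outcome string ('w'/'t'/'l'), player always R."""
    ai = {"w": "S", "t": "R", "l": "P"}
    return game_from_hands("R" * len(outs), "".join(ai[o] for o in outs), player_id)


@pytest.fixture(scope="session")
def toy_uw_game() -> GameRecord:
    """12-round transcript with wins at rounds 1,3,5,8,10 and post-win
    own-transitions U,U,U,C,U -- the hand-worked oracle for the U|w trace."""
    return game_from_hands("RPRPRPSRRSRR", "SSSSSSSSPPPR")


@pytest.fixture(scope="session")
def nme_games_small():
    from rrps.simulate import play_games
    return play_games("nme", 10, n_rounds=300, seed=123)


@pytest.fixture(scope="session")
def rs1_games_small():
    from rrps.simulate import play_games
    return play_games("rs1", 10, n_rounds=300, seed=321)
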