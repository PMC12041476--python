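"""Dynamic probability traces, RSS, shuffle nulls and repertoire calls.

The core oracle is an independent straight-from-the-description
implementation (explicit loops over conditioning events) checked against the
vectorized pipeline on hand-built transcripts.
"""

import numpy as np
import pytest

from rrps.game import GameRecord
from rrps.repertoire import (all_traces, detect_repertoire, prob_trace,
                             shuffle_null, time_above_threshold)
from rrps.rules import RULES, RULE_NAMES, condition_array, action_array
from .conftest import game_from_hands, game_from_outcomes

UW = RULES[2]  # DCU|wtl : U|w
assert UW.name == "DCU|wtl:U|w"


def oracle_trace(game: GameRecord, rule, B: int) -> np.ndarray:
    """Brute-force reference: sliding windows over conditioning events,
    estimates anchored at each window's first event round, linear
    interpolation between anchors, edges held."""
    cond = condition_array(game, rule.framework.condition_class)
    act = action_array(game, rule.framework.action_class)
    events = [(i + 1, act[i]) for i in range(len(cond)) if cond[i] == rule.condition]
    if len(events) < B:
        return np.full(game.n_rounds, np.nan)
    anchors, ests = [], []
    for m in range(len(events) - B + 1):
        window = events[m:m + B]
        anchors.append(window[0][0])
        ests.append(sum(1 for _, a in window if a == rule.action) / B)
    out = np.empty(game.n_rounds)
    for k in range(1, game.n_rounds + 1):
        if k <= anchors[0]:
            out[k - 1] = ests[0]
        elif k >= anchors[-1]:
            out[k - 1] = ests[-1]
        else:
            j = max(i for i, a in enumerate(anchors) if a <= k)
            a0, a1 = anchors[j], anchors[j + 1]
            out[k - 1] = ests[j] + (ests[j + 1] - ests[j]) * (k - a0) / (a1 - a0)
    return out


def test_toy_transcript_matches_hand_computation(toy_uw_game):
    """Wins at rounds 1,3,5,8,10 followed by transitions U,U,U,C,U: the three
    B=3 windows give estimates 1, 2/3, 2/3 anchored at rounds 1, 3, 5."""
    t = prob_trace(toy_uw_game, UW, B=3)
    np.testing.assert_array_equal(t.anchor_rounds, [1, 3, 5])
    np.testing.assert_allclose(t.anchor_values, [1.0, 2 / 3, 2 / 3])
    expected = np.array([1.0, 5 / 6] + [2 / 3] * 10)
    np.testing.assert_allclose(t.values, expected)
    assert time_above_threshold(t, 0.8) == 2  # rounds 1 and 2 only
    np.testing.assert_allclose(t.values, oracle_trace(toy_uw_game, UW, 3))


def test_all_matching_window_gives_one(toy_uw_game):
    # the first window (wins 1,3,5 -> U,U,U) estimates exactly 3/3
    t = prob_trace(toy_uw_game, UW, B=3)
    assert t.anchor_values[0] == 1.0


def test_trace_matches_oracle_on_simulated_games(rs1_games_small):
    game = rs1_games_small[0]
    for rule in (RULES[2], RULES[10], RULES[33], RULES[53]):
        got = prob_trace(game, rule, B=3).values
        want = oracle_trace(game, rule, 3)
        np.testing.assert_allclose(got, want, err_msg=rule.name)


def test_raw_estimates_quantized(nme_games_small):
    allowed = {0.0, 1 / 3, 2 / 3, 1.0}
    for t in all_traces(nme_games_small[0], B=3):
        assert {round(v, 10) for v in t.anchor_values} <= {round(a, 10) for a in allowed}


def test_trace_undefined_below_B_occurrences():
    g = game_from_outcomes("tttttttt")  # no wins at all
    t = prob_trace(g, UW, B=3)
    assert not t.defined
    assert np.isnan(t.values).all()


def test_time_above_threshold_basics():
    t = prob_trace(game_from_outcomes("w" * 20 + "t"), UW, B=3)  # always R: copy
    assert time_above_threshold(t, 0.8) == 0  # all-copy: p(U|w) = 0
    # constant-1 trace via a dedicated game: upgrade after every win
    g = game_from_hands("RPSRPSRPSRPS", "SSSSSSSSSSSS")
    tt = prob_trace(g, UW, B=3)
    assert time_above_threshold(tt, 0.8) == g.n_rounds
    assert time_above_threshold(tt, 1.1) == 0


def test_tat_monotone_in_threshold(rs1_games_small):
    t = prob_trace(rs1_games_small[0], UW, B=3)
    tats = [time_above_threshold(t, thr) for thr in (0.5, 0.7, 0.8, 0.9)]
    assert tats == sorted(tats, reverse=True)


def test_shuffle_preserves_round_triples(nme_games_small):
    g = nme_games_small[0]
    perm = np.random.default_rng(0).permutation(g.n_rounds)
    gp = g.permuted(perm)
    a = sorted(zip(g.hp.tolist(), g.ai.tolist(), g.out.tolist()))
    b = sorted(zip(gp.hp.tolist(), gp.ai.tolist(), gp.out.tolist()))
    assert a == b


def test_shuffle_null_shapes_and_validation(nme_games_small):
    null = shuffle_null(nme_games_small[0], UW, n_shuffles=20, rng=1)
    assert null.shape == (20,)
    assert np.all(null >= 0)
    with pytest.raises(ValueError):
        shuffle_null(nme_games_small[0], UW, n_shuffles=0, rng=1)


def test_deterministic_rule_user_flagged_in_repertoire():
    """U|w, C|t, D|l played deterministically all game is detected."""
    from rrps.simulate import make_rs_ruleset, RuleSwitchingPlayer, NMEPlayer, play_game
    rs = make_rs_ruleset((2, 1, 0), A=1.0, framework="DCU|wtl")
    g = play_game(RuleSwitchingPlayer([rs]), ai=None, opponent=NMEPlayer(),
                  n_rounds=300, rng=3)
    res = detect_repertoire(g, n_shuffles=100, rng=4)
    flagged = {r.rule.name for r in res if r.in_repertoire}
    assert {"DCU|wtl:U|w", "DCU|wtl:C|t", "DCU|wtl:D|l"} <= flagged


def test_planted_rules_recovered_in_rs_games(rs1_games_small):
    """Dominant planted rules are flagged in > 80% of simulated games."""
    from rrps.simulate import bundled_ruleset_specs
    planted = []
    for rs in bundled_ruleset_specs("rs1"):
        csym = rs.framework.condition_symbols()
        asym = rs.framework.action_symbols()
        planted += [f"{rs.framework.name}:{asym[a]}|{csym[c]}"
                    for c, a in rs.dominant_rules()]
    rng = np.random.default_rng(11)
    hits = []
    for g in rs1_games_small:
        res = detect_repertoire(g, n_shuffles=100, rng=int(rng.integers(2**31)))
        flagged = {r.rule.name for r in res if r.in_repertoire}
        hits += [p in flagged for p in planted]
    assert np.mean(hits) > 0.8


def test_results_cover_all_rules_with_flags_consistent(nme_games_small):
    res = detect_repertoire(nme_games_small[0], n_shuffles=50, rng=9)
    assert len(res) == 54
    assert [r.rule.name for r in res] == list(RULE_NAMES)
    for r in res:
        if np.isnan(r.percentile):
            assert not r.in_repertoire
        else:
            assert r.in_repertoire == (r.percentile >= r.percentile_cut)
            assert 0 <= r.rss <= 300


def test_threshold_percentile_sensitivity(rs1_games_small):
    """Moving thr within [0.75, 0.9] and the cut within [96, 99] changes the
    flagged set quantitatively but planted rules keep being detected."""
    g = rs1_games_small[1]
    flagged = {}
    for thr, cut in ((0.75, 96.0), (0.8, 98.0), (0.9, 99.0)):
        res = detect_repertoire(g, thr=thr, percentile_cut=cut, n_shuffles=100, rng=5)
        flagged[(thr, cut)] = {r.rule.name for r in res if r.in_repertoire}
    # the strictest setting still finds something the planted player uses
    assert flagged[(0.9, 99.0)]
    assert flagged[(0.9, 99.0)] <= flagged[(0.75, 96.0)] | flagged[(0.8, 98.0)] | flagged[(0.9, 99.0)]
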