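"""Rulesets, switch schedules, rule-switching players and the game runner."""

import numpy as np
import pytest

from rrps.game import Hand
from rrps.rules import FRAMEWORKS
from rrps.simulate import (NMEPlayer, RuleSwitchingPlayer, SwitchSchedule,
                           bundled_ruleset_specs, make_rs_ruleset, play_game,
                           play_games, switch_schedule, framework_by_name)


def test_rs_ruleset_rows():
    rs = make_rs_ruleset((1, None, 2), A=0.9, framework="DCU|wtl")
    np.testing.assert_allclose(rs.matrix[0], [0.05, 0.9, 0.05])
    np.testing.assert_allclose(rs.matrix[1], [1 / 3] * 3)
    np.testing.assert_allclose(rs.matrix[2], [0.05, 0.05, 0.9])
    np.testing.assert_allclose(rs.matrix.sum(axis=1), 1.0, atol=1e-12)


@pytest.mark.parametrize("A", [0.2, 1 / 3, 1.5])
def test_rs_ruleset_rejects_non_dominant_A(A):
    with pytest.raises(ValueError):
        make_rs_ruleset((0, 1, 2), A=A)


def test_bundled_specs_have_dominant_and_equiprobable_rows():
    for name in ("rs1", "rs2"):
        rulesets = bundled_ruleset_specs(name)
        assert len(rulesets) == 2
        frameworks = {rs.framework for rs in rulesets}
        assert len(frameworks) == 2
        for rs in rulesets:
            assert rs.dominant_rules(min_p=0.5)
        has_equiprobable = any(
            np.allclose(rs.matrix[c], 1 / 3) for rs in rulesets for c in range(3)
        )
        assert has_equiprobable, "expected at least one equiprobable row"


def test_switch_schedule_degenerate_uniform():
    s = switch_schedule(mean_interval=10, jitter=0, n_rounds=300, rng=0)
    assert s.switch_rounds == tuple(range(10, 300, 10))


def test_switch_schedule_mean_and_count():
    rng = np.random.default_rng(5)
    intervals = []
    counts = []
    for _ in range(200):
        s = switch_schedule(11, 3, 300, rng)
        r = np.array(s.switch_rounds)
        intervals += list(np.diff(r))
        counts.append(len(r))
    assert abs(np.mean(intervals) - 11) < 0.2
    assert abs(np.mean(counts) - 300 / 11) < 1.5
    assert all(8 <= d <= 14 for d in intervals)


def test_switch_schedule_validation():
    with pytest.raises(ValueError):
        switch_schedule(0, 0, 300, rng=0)
    with pytest.raises(ValueError):
        switch_schedule(5, 5, 300, rng=0)


def test_stationary_conditional_play_matches_matrix():
    """A single-ruleset player's long-run conditionals match its matrix."""
    rs = make_rs_ruleset((2, 1, 0), A=0.9, framework="DCU|wtl")
    player = RuleSwitchingPlayer([rs])
    g = play_game(player, ai=None, opponent=NMEPlayer(), n_rounds=10_000, rng=9)
    from rrps.rules import condition_array, action_array
    fw = framework_by_name("DCU|wtl")
    cond = condition_array(g, fw.condition_class)
    act = action_array(g, fw.action_class)
    for c in range(3):
        sel = act[cond == c]
        for a in range(3):
            assert abs(np.mean(sel == a) - rs.matrix[c, a]) < 0.03


def test_switch_at_round_changes_conditionals():
    """Before/after a scheduled switch the realized conditionals follow the
    respective active matrices."""
    fw = framework_by_name("DCU|rps")
    rs_a = make_rs_ruleset((0, 0, 0), A=0.95, framework=fw)   # always downgrade
    rs_b = make_rs_ruleset((2, 2, 2), A=0.95, framework=fw)   # always upgrade
    sched = SwitchSchedule((101,), 100.0, 0)
    player = RuleSwitchingPlayer([rs_a, rs_b], sched)
    g = play_game(player, ai=None, opponent=NMEPlayer(), n_rounds=300, rng=13)
    from rrps.rules import action_array
    act = action_array(g, fw.action_class)  # rounds 2..300
    before = act[: 98]          # actions at rounds 2..99, safely pre-switch
    after = act[101:]           # actions from round 103 on
    assert np.mean(before == 0) > 0.85
    assert np.mean(after == 2) > 0.85


def test_first_round_is_unconditioned():
    rs = make_rs_ruleset((0, 0, 0), A=1.0, framework="DCU|wtl")
    counts = np.zeros(3)
    for seed in range(300):
        player = RuleSwitchingPlayer([rs])
        g = play_game(player, ai=None, opponent=NMEPlayer(), n_rounds=1, rng=seed)
        counts[g.hp[0]] += 1
    assert counts.min() > 60  # roughly uniform over 300 draws


def test_play_game_round_count_and_metadata():
    games = play_games("rs1", 1, n_rounds=300, seed=17)
    g = games[0]
    assert g.n_rounds == 300
    assert g.metadata["player_type"] == "rule_switching"
    assert "true_switch_rounds" in g.metadata
    assert np.asarray(g.metadata["ai_confidence"]).shape == (300, 3)
    sw = g.metadata["true_switch_rounds"]
    assert all(1 <= s <= 300 for s in sw)
    assert all(b > a for a, b in zip(sw, sw[1:]))


def test_nme_hand_frequencies():
    g = play_game(NMEPlayer(), ai=None, opponent=NMEPlayer(), n_rounds=30_000, rng=19)
    p = np.bincount(g.hp, minlength=3) / g.n_rounds
    sigma = np.sqrt((1 / 3) * (2 / 3) / g.n_rounds)
    assert np.all(np.abs(p - 1 / 3) < 3 * sigma + 1e-12)


def test_transcripts_bit_identical_across_runs():
    a = play_games("rs1", 2, n_rounds=300, seed=23)
    b = play_games("rs1", 2, n_rounds=300, seed=23)
    for x, y in zip(a, b):
        assert np.array_equal(x.hp, y.hp) and np.array_equal(x.ai, y.ai)
        assert x.metadata["true_switch_rounds"] == y.metadata["true_switch_rounds"]


def test_dcu_rps_restates_rps_rps():
    """A DCU|rps matrix and its RPS|rps restatement induce the same
    hand-given-own-hand conditional distribution."""
    dcu = make_rs_ruleset((1, None, 2), A=0.9, framework="DCU|rps")
    # p(next hand h | own hand c) = p(transition t | c) with h = apply(c, t)
    from rrps.game import apply_transition
    hand_matrix = np.zeros((3, 3))
    for c in range(3):
        for t in range(3):
            hand_matrix[c, int(apply_transition(c, t))] += dcu.matrix[c, t]
    # simulate under the DCU description and compare realized hand conditionals
    player = RuleSwitchingPlayer([dcu])
    g = play_game(player, ai=None, opponent=NMEPlayer(), n_rounds=10_000, rng=29)
    from rrps.rules import condition_array
    cond = g.hp[:-1]
    nxt = g.hp[1:]
    for c in range(3):
        sel = nxt[cond == c]
        for h in range(3):
            assert abs(np.mean(sel == h) - hand_matrix[c, h]) < 0.03
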