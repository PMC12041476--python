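"""The 1521-feature vector, stability, clustering, and descriptive statistics."""

import numpy as np
import pandas as pd
import pytest

from rrps.features import (N_FEATURES, assemble_features, cluster_repertoire,
                           corr_subcategory, feature_ai_confidence,
                           feature_conditional_outcome, feature_corr,
                           feature_metadata, feature_std, features_table,
                           response_time_by_outcome, win_autocorrelation)
from rrps.features import test_retest as retest  # avoid pytest collecting the library name
from rrps.repertoire import ProbTrace, all_traces
from rrps.rules import RULES
from .conftest import game_from_hands, game_from_outcomes


def _trace(rule, values):
    v = np.asarray(values, float)
    return ProbTrace(rule, v, 3, np.arange(1, len(v) + 1), v)


def test_feature_vector_partition(rs1_games_small):
    vec = assemble_features(rs1_games_small[0])
    assert len(vec) == N_FEATURES == 1521
    meta = feature_metadata()
    counts = meta["category"].value_counts()
    assert counts["A"] == 54 and counts["B"] == 1431
    assert counts["C"] == 27 and counts["D"] == 9
    assert list(meta["name"]) == list(vec.index)


def test_feature_ranges(rs1_games_small):
    vec = assemble_features(rs1_games_small[1])
    meta = feature_metadata().set_index("name")
    b = vec[meta["category"] == "B"].dropna()
    assert ((b >= -1 - 1e-12) & (b <= 1 + 1e-12)).all()
    for cat in ("A", "C", "D"):
        v = vec[meta["category"] == cat].dropna()
        assert (v >= -1e-12).all() and (v <= 1 + 1e-12).all()


def test_feature_std_closed_forms():
    traces = [_trace(r, np.zeros(10)) for r in RULES]
    traces[0] = _trace(RULES[0], np.tile([0.0, 1.0], 50))
    s = feature_std(traces)
    assert len(s) == 54
    assert np.isclose(s.iloc[0], 0.5)       # alternating 0/1: population SD 1/2
    assert (s.iloc[1:] == 0.0).all()        # constant traces


def test_corr_subcategories():
    uw = next(r for r in RULES if r.name == "DCU|wtl:U|w")
    dw = next(r for r in RULES if r.name == "DCU|wtl:D|w")
    ut = next(r for r in RULES if r.name == "DCU|wtl:U|t")
    rw = next(r for r in RULES if r.name == "RPS|wtl:R|w")
    rt = next(r for r in RULES if r.name == "RPS|wtl:R|t")
    rs_ = next(r for r in RULES if r.name == "DCU|rps:D|r")
    assert corr_subcategory(uw, dw) == 1
    assert corr_subcategory(uw, ut) == 2
    assert corr_subcategory(uw, rw) == 3   # shared condition class wtl, same w
    assert corr_subcategory(uw, rt) == 4
    assert corr_subcategory(uw, rs_) == 5


def test_feature_corr_count_and_antagonist_rules():
    """A strict alternating-rule user makes p(D|w) and p(U|w) anticorrelated."""
    rng = np.random.default_rng(0)
    traces = [_trace(r, rng.uniform(size=40)) for r in RULES]
    up = np.tile([1.0, 1, 1, 0, 0], 8)  # alternating episodes, same length 40
    traces[2] = _trace(RULES[2], up)        # U|w
    traces[0] = _trace(RULES[0], 1 - up)    # D|w
    c = feature_corr(traces)
    assert len(c) == 1431
    name = [n for n in c.index if "DCU|wtl:D|w,DCU|wtl:U|w" in n]
    assert len(name) == 1 and c[name[0]] < -0.95


def test_ai_confidence_features_constant():
    g = game_from_outcomes("wtlwtlwtlwtl")
    g.metadata["ai_confidence"] = np.full((12, 3), 1 / 3)
    c = feature_ai_confidence(g)
    assert len(c) == 27
    np.testing.assert_allclose(c.dropna().to_numpy(), 1 / 3)


def test_ai_confidence_features_grouped_means():
    g = game_from_outcomes("wlwlwl")
    conf = np.zeros((6, 3))
    conf[:, 0] = [0.2, 0.9, 0.1, 0.7, 0.3, 0.5]
    g.metadata["ai_confidence"] = conf
    c = feature_ai_confidence(g)
    # rounds following w (rounds 2,4,6) have R-components 0.9, 0.7, 0.5
    assert np.isclose(c["C:confR|w"], 0.7)
    # rounds following l (rounds 3,5) have R-components 0.1, 0.3
    assert np.isclose(c["C:confR|l"], 0.2)
    assert np.isnan(c["C:confR|t"])  # no ties occurred


def test_conditional_outcome_features():
    g = game_from_outcomes("tttttt")
    d = feature_conditional_outcome(g)
    assert len(d) == 9
    assert d["D:p(t|t)"] == 1.0
    assert d["D:p(w|t)"] == 0.0
    assert np.isnan(d["D:p(w|l)"])  # no losses to condition on
    g2 = game_from_outcomes("wtlwlttwlw")
    d2 = feature_conditional_outcome(g2).to_numpy().reshape(3, 3)
    sums = np.nansum(d2, axis=1)
    np.testing.assert_allclose(sums[~np.isnan(d2).all(axis=1)], 1.0)


def test_test_retest_identity_and_noise():
    rng = np.random.default_rng(1)
    f1 = pd.DataFrame(rng.normal(size=(12, 30)),
                      index=[f"p{i}" for i in range(12)],
                      columns=feature_metadata()["name"][:30])
    tr = retest(f1, f1.copy(), n_shuffles=30, rng=2)
    np.testing.assert_allclose(tr.per_feature.dropna(), 1.0)
    f2 = pd.DataFrame(rng.normal(size=(12, 30)), index=f1.index, columns=f1.columns)
    tr2 = retest(f1, f2, n_shuffles=30, rng=3)
    assert abs(tr2.category_mean.mean()) < 0.2
    assert tr2.null_category_means.shape[0] == 30


def test_stable_players_beat_identity_shuffle_null():
    """Players with stable planted repertoires show test-retest correlation
    above the 95th percentile of the identity-shuffle null (categories A/B)."""
    from rrps.simulate import (RuleSwitchingPlayer, bundled_ruleset_specs,
                               play_game, switch_schedule)
    from rrps.ai import PerceptronAI
    root = np.random.default_rng(42)
    rows1, rows2 = {}, {}
    for p in range(8):
        # a stable individual = same ruleset family across both measurements,
        # different games; individuals differ by which bundled spec they use
        spec = "rs1" if p % 2 == 0 else "rs2"
        for rows, seed in ((rows1, 1000 + p), (rows2, 2000 + p)):
            rng = np.random.default_rng(seed)
            player = RuleSwitchingPlayer(bundled_ruleset_specs(spec),
                                         switch_schedule(11, 3, 300, rng))
            g = play_game(player, ai=PerceptronAI(rng_seed=seed), n_rounds=300,
                          rng=rng, player_id=f"p{p}")
            rows[f"p{p}"] = assemble_features(g)
    f1 = pd.DataFrame(rows1).T
    f2 = pd.DataFrame(rows2).T
    tr = retest(f1, f2, n_shuffles=50, rng=7)
    for cat in ("A", "B"):
        null95 = np.nanpercentile(tr.null_category_means[cat], 95)
        assert tr.category_mean[cat] > null95


def test_cluster_repertoire_recovers_planted_archetypes():
    rng = np.random.default_rng(5)
    a = np.zeros(54); a[:6] = 100.0
    b = np.zeros(54); b[30:38] = 100.0
    X = np.vstack([a + rng.normal(0, 3, 54) for _ in range(20)]
                  + [b + rng.normal(0, 3, 54) for _ in range(20)])
    df = pd.DataFrame(np.clip(X, 0, 100), index=[f"p{i}" for i in range(40)])
    out = cluster_repertoire(df, n_clusters=2, rng=6)
    from sklearn.metrics import adjusted_rand_score
    truth = [0] * 20 + [1] * 20
    assert adjusted_rand_score(truth, out.labels) > 0.9
    assert out.embedding.shape == (40, 2)
    assert out.rule_pattern.shape == (2, 54)


def test_cluster_identical_players_single_cluster_pattern():
    df = pd.DataFrame(np.tile(np.linspace(0, 100, 54), (10, 1)))
    out = cluster_repertoire(df, n_clusters=2, rng=1)
    # degenerate geometry: the per-cluster repertoire patterns coincide
    assert np.allclose(out.rule_pattern.to_numpy().std(axis=0), 0.0)


def test_win_autocorrelation_periodic_and_calibration():
    g = game_from_outcomes("wl" * 30)
    ac = win_autocorrelation(g, max_lag=6, n_shuffles=50, rng=2)
    assert ac.loc[0, "ac"] == 1.0
    assert ac.loc[1, "ac"] < -0.9 and ac.loc[2, "ac"] > 0.9
    # iid outcomes stay inside the shuffle band at >= 95% of lags (jointly
    # over a few games to damp binomial noise)
    rng = np.random.default_rng(3)
    inside = []
    for seed in range(6):
        outs = "".join(rng.choice(list("wtl"), size=300))
        gg = game_from_outcomes(outs)
        a = win_autocorrelation(gg, max_lag=15, n_shuffles=100, rng=seed)
        inside += list((a["ac"] >= a["lo"]) & (a["ac"] <= a["hi"]))[1:]
    assert np.mean(inside) >= 0.9


def test_response_time_by_outcome_fixture():
    rt = np.array([500.0, 700, 500, 700, 500, 700, 500])
    # outcomes w,l,w,l,w,t,w; RT at round k: 700 after wins, 500 otherwise
    g2 = game_from_hands("RRRRRRR", "SPSPSRS", rt_ms=rt)
    out = response_time_by_outcome(g2)
    assert out.loc["w", "mean_rt_ms"] == 700.0
    assert out.loc["l", "mean_rt_ms"] == 500.0
    assert out["n"].sum() == 6  # rounds 2..7 partition by previous outcome


def test_features_table_shape(rs1_games_small):
    df = features_table(rs1_games_small[:3])
    assert df.shape == (3, 1521)
    assert df.index.tolist() == [g.player_id for g in rs1_games_small[:3]]
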