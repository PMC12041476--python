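"""The 1521-feature behavioral vector and its supporting analyses.

Per game, four feature categories are assembled from the 54 dynamic
conditional-probability traces and the AI's internal state:

* **A** -- the standard deviation of each rule's trace (54 features);
* **B** -- the Pearson correlation between every unordered pair of traces
  (54 x 53 / 2 = 1431 features), each pair labeled with a correlation
  subcategory 1-5 by how the two rules' frameworks and conditions relate;
* **C** -- the AI's decision confidence (softmax of its three perceptron
  outputs) averaged over rounds following each of the 9 lag-1 conditions
  (9 x 3 = 27 features);
* **D** -- the outcome-transition probabilities p(outcome_k | outcome_{k-1})
  (3 x 3 = 9 features);

for a total of 54 + 1431 + 27 + 9 = 1521 named features.  Also here:
test-retest stability with an identity-shuffle null, clustering of
repertoire patterns (t-SNE embedding + agglomerative clustering of the 54
RSS percentiles), win autocorrelation with a round-shuffle band, and
response times split by previous outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .game import GameRecord, Outcome
from .repertoire import ProbTrace, all_traces, DEFAULT_B
from .rules import FRAMEWORKS, RULES, RULE_NAMES, Rule

__all__ = [
    "N_FEATURES",
    "feature_std",
    "feature_corr",
    "corr_subcategory",
    "feature_ai_confidence",
    "feature_conditional_outcome",
    "assemble_features",
    "feature_metadata",
    "features_table",
    "test_retest",
    "cluster_repertoire",
    "win_autocorrelation",
    "response_time_by_outcome",
]

N_FEATURES = 1521
_CONF_CONDITIONS = ("w", "t", "l", "r", "p", "s", "r_A", "p_A", "s_A")
_OUT_SYMS = ("w", "t", "l")


def feature_std(traces: Sequence[ProbTrace]) -> pd.Series:
    """Category A: per-rule population standard deviation of the trace (54 values)."""
    vals = np.full(54, np.nan)
    for i, t in enumerate(traces):
        v = t.values[~np.isnan(t.values)]
        if len(v):
            vals[i] = float(np.std(v))
    return pd.Series(vals, index=[f"A:sd:{r.name}" for r in RULES])


def corr_subcategory(r1: Rule, r2: Rule) -> int:
    """Correlation subcategory 1-5 for an unordered rule pair.

    1 same framework, same condition; 2 same framework, different condition;
    3 different frameworks sharing the condition class, same condition;
    4 different frameworks sharing the condition class, different condition;
    5 frameworks that do not share a condition class.
    """
    same_fw = r1.framework == r2.framework
    same_cc = r1.framework.condition_class == r2.framework.condition_class
    same_cond = same_cc and r1.condition == r2.condition
    if same_fw:
        return 1 if same_cond else 2
    if same_cc:
        return 3 if same_cond else 4
    return 5


def feature_corr(traces: Sequence[ProbTrace]) -> pd.Series:
    """Category B: Pearson correlation of every unordered trace pair (1431 values).

    Traces are interpolated over the full game, so a pair overlaps either on
    every round or not at all (when either trace is undefined).  Pairs with
    fewer than 3 overlapping rounds, or with a zero-variance member, are NaN.
    Whether a rule is in-repertoire is deliberately ignored.
    """
    n = len(traces[0].values)
    mat = np.vstack([t.values for t in traces])
    defined = ~np.isnan(mat).any(axis=1)
    sd = np.nanstd(mat, axis=1)
    usable = defined & (sd > 0) & (np.sum(~np.isnan(mat), axis=1) >= 3)
    cor = np.full((54, 54), np.nan)
    idx = np.flatnonzero(usable)
    if len(idx) >= 2:
        cor_block = np.corrcoef(mat[idx])
        cor[np.ix_(idx, idx)] = cor_block
    names, vals = [], []
    for i in range(54):
        for j in range(i + 1, 54):
            sub = corr_subcategory(RULES[i], RULES[j])
            names.append(f"B{sub}:corr:{RULE_NAMES[i]},{RULE_NAMES[j]}")
            vals.append(cor[i, j])
    return pd.Series(vals, index=names)


def feature_ai_confidence(game: GameRecord) -> pd.Series:
    """Category C: mean AI confidence components following each lag-1 condition (27 values).

    For each of the 9 conditions (previous outcome w/t/l, previous own hand
    r/p/s, previous AI hand r_A/p_A/s_A) the mean of each of the 3 softmax
    confidence components over the following rounds.  NaN where the condition
    never occurs.  Requires per-round AI confidence in the game metadata.
    """
    conf = np.asarray(game.metadata.get("ai_confidence"))
    if conf is None or conf.ndim != 2 or conf.shape != (game.n_rounds, 3):
        raise ValueError("game metadata lacks per-round 'ai_confidence' (n x 3)")
    nxt = conf[1:]  # confidence at round k, conditioned on round k-1
    cond_arrays = {
        "w": game.out[:-1] == 0, "t": game.out[:-1] == 1, "l": game.out[:-1] == 2,
        "r": game.hp[:-1] == 0, "p": game.hp[:-1] == 1, "s": game.hp[:-1] == 2,
        "r_A": game.ai[:-1] == 0, "p_A": game.ai[:-1] == 1, "s_A": game.ai[:-1] == 2,
    }
    names, vals = [], []
    for sym in _CONF_CONDITIONS:
        mask = cond_arrays[sym]
        for comp, hand in enumerate("RPS"):
            names.append(f"C:conf{hand}|{sym}")
            vals.append(float(np.mean(nxt[mask, comp])) if mask.any() else np.nan)
    return pd.Series(vals, index=names)


def feature_conditional_outcome(game: GameRecord) -> pd.Series:
    """Category D: p(outcome at k | outcome at k-1) for the 9 ordered outcome pairs."""
    if game.n_rounds < 2:
        raise ValueError("need at least 2 rounds")
    prev, curr = game.out[:-1], game.out[1:]
    names, vals = [], []
    for i, a in enumerate(_OUT_SYMS):
        mask = prev == i
        denom = int(mask.sum())
        for j, b in enumerate(_OUT_SYMS):
            names.append(f"D:p({b}|{a})")
            vals.append(float(np.sum(curr[mask] == j)) / denom if denom else np.nan)
    return pd.Series(vals, index=names)


def assemble_features(game: GameRecord, B: int = DEFAULT_B,
                      traces: Sequence[ProbTrace] | None = None) -> pd.Series:
    """The full 1521-feature vector for one game, partitioned 54/1431/27/9."""
    if traces is None:
        traces = all_traces(game, B=B)
    vec = pd.concat([
        feature_std(traces),
        feature_corr(traces),
        feature_ai_confidence(game),
        feature_conditional_outcome(game),
    ])
    assert len(vec) == N_FEATURES, f"feature count {len(vec)} != {N_FEATURES}"
    return vec


def feature_metadata() -> pd.DataFrame:
    """Name, category (A-D) and correlation subcategory (B only) of each feature."""
    rows = []
    for r in RULES:
        rows.append((f"A:sd:{r.name}", "A", None))
    for i in range(54):
        for j in range(i + 1, 54):
            sub = corr_subcategory(RULES[i], RULES[j])
            rows.append((f"B{sub}:corr:{RULE_NAMES[i]},{RULE_NAMES[j]}", "B", sub))
    for sym in _CONF_CONDITIONS:
        for hand in "RPS":
            rows.append((f"C:conf{hand}|{sym}", "C", None))
    for a in _OUT_SYMS:
        for b in _OUT_SYMS:
            rows.append((f"D:p({b}|{a})", "D", None))
    df = pd.DataFrame(rows, columns=["name", "category", "subcategory"])
    assert len(df) == N_FEATURES
    return df


def features_table(games: Sequence[GameRecord], B: int = DEFAULT_B) -> pd.DataFrame:
    """One row per game (indexed by player_id), 1521 named feature columns."""
    return pd.DataFrame(
        {g.player_id: assemble_features(g, B=B) for g in games}
    ).T.rename_axis("player_id")


# -- stability, clustering, descriptive statistics -------------------------

@dataclass
class TestRetest:
    """Across-player test-retest correlations, per feature and per category."""

    per_feature: pd.Series          # correlation between measurement 1 and 2
    category_mean: pd.Series        # mean correlation per category A-D
    null_category_means: pd.DataFrame  # one row per identity shuffle


def _across_player_corr(f1: pd.DataFrame, f2: pd.DataFrame) -> pd.Series:
    out = {}
    for col in f1.columns:
        a, b = f1[col].to_numpy(float), f2[col].to_numpy(float)
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
            out[col] = np.nan
        else:
            out[col] = float(np.corrcoef(a[ok], b[ok])[0, 1])
    return pd.Series(out)


def test_retest(
    features_game1: pd.DataFrame,
    features_game2: pd.DataFrame,
    n_shuffles: int = 200,
    rng: np.random.Generator | int | None = None,
) -> TestRetest:
    """Stability of features across two measurements of the same players.

    Both frames must be indexed by player_id with identical feature columns.
    The null permutes the player identity of the second measurement,
    ``n_shuffles`` times (default 200).
    """
    if len(features_game1) < 3:
        raise ValueError("need at least 3 players")
    f2 = features_game2.loc[features_game1.index]
    meta = feature_metadata().set_index("name")["category"]
    rng = np.random.default_rng(rng)

    per_feature = _across_player_corr(features_game1, f2)
    category_mean = per_feature.groupby(meta.loc[per_feature.index]).mean()

    null_rows = []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(f2))
        f2s = pd.DataFrame(f2.to_numpy()[perm], index=f2.index, columns=f2.columns)
        pf = _across_player_corr(features_game1, f2s)
        null_rows.append(pf.groupby(meta.loc[pf.index]).mean())
    return TestRetest(per_feature, category_mean, pd.DataFrame(null_rows))


@dataclass
class RepertoireClusters:
    embedding: np.ndarray       # (n_players, 2) t-SNE coordinates
    labels: np.ndarray          # agglomerative cluster label per player
    rule_pattern: pd.DataFrame  # per cluster, fraction of members with rule in-repertoire


def cluster_repertoire(
    percentiles: pd.DataFrame,
    n_clusters: int = 9,
    percentile_cut: float = 98.0,
    rng: np.random.Generator | int | None = 0,
) -> RepertoireClusters:
    """Cluster players by their 54 RSS percentiles and embed them in 2-D.

    Cluster labels come from agglomerative (Ward) clustering of the raw
    percentile features; the t-SNE embedding is for visualization only.
    ``percentiles`` is players x 54 (canonical rule order); NaNs (rules with
    undefined traces) are treated as percentile 0 for this analysis.
    """
    from sklearn.cluster import AgglomerativeClustering
    from sklearn.manifold import TSNE

    X = percentiles.to_numpy(float)
    X = np.where(np.isnan(X), 0.0, X)
    n = len(X)
    if n < n_clusters:
        raise ValueError("need at least n_clusters players")
    seed = int(np.random.default_rng(rng).integers(2**31))
    perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    if np.allclose(X, X[0]):
        emb = np.zeros((n, 2))  # all players identical: nothing to embed
    else:
        emb = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                   init="pca").fit_transform(X)
    labels = AgglomerativeClustering(n_clusters=n_clusters).fit_predict(X)
    flags = pd.DataFrame(X >= percentile_cut, index=percentiles.index,
                         columns=percentiles.columns)
    pattern = flags.groupby(labels).mean()
    pattern.index.name = "cluster"
    return RepertoireClusters(embedding=emb, labels=labels, rule_pattern=pattern)


def win_autocorrelation(
    game: GameRecord,
    max_lag: int = 15,
    n_shuffles: int = 200,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Lagged autocorrelation of the binary win indicator, with a shuffle band.

    Returns a frame indexed by lag 0..max_lag with columns ``ac`` and the
    round-shuffle 95% null band ``lo``/``hi`` (lag 0 is identically 1).
    """
    if game.n_rounds < 20:
        raise ValueError("need at least 20 rounds")
    rng = np.random.default_rng(rng)
    w = (game.out == Outcome.W).astype(float)

    def _ac(x: np.ndarray) -> np.ndarray:
        out = np.empty(max_lag + 1)
        out[0] = 1.0
        for lag in range(1, max_lag + 1):
            a, b = x[:-lag], x[lag:]
            if np.std(a) == 0 or np.std(b) == 0:
                out[lag] = np.nan
            else:
                out[lag] = float(np.corrcoef(a, b)[0, 1])
        return out

    ac = _ac(w)
    null = np.vstack([_ac(rng.permutation(w)) for _ in range(n_shuffles)])
    lo = np.nanpercentile(null, 2.5, axis=0)
    hi = np.nanpercentile(null, 97.5, axis=0)
    return pd.DataFrame({"ac": ac, "lo": lo, "hi": hi},
                        index=pd.RangeIndex(max_lag + 1, name="lag"))


def response_time_by_outcome(game: GameRecord) -> pd.DataFrame:
    """Mean and median response time at round k, grouped by the outcome of round k-1."""
    if game.n_rounds < 2:
        raise ValueError("need at least 2 rounds")
    prev = game.out[:-1]
    rt = game.rt_ms[1:]
    rows = {}
    for i, sym in enumerate(_OUT_SYMS):
        sel = rt[prev == i]
        rows[sym] = {
            "n": int(len(sel)),
            "mean_rt_ms": float(np.mean(sel)) if len(sel) else np.nan,
            "median_rt_ms": float(np.median(sel)) if len(sel) else np.nan,
        }
    return pd.DataFrame(rows).T.rename_axis("prev_outcome")
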