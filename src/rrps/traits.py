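"""Trait-score stage: synthetic AQ28 generator, mass correlations, nested-CV Lasso.

The AQ28 (Abridged Autism Quotient) is a 28-item self-report scale with five
subscores -- Social Skills, Imagination, Routine, Switch, and Numbers and
Patterns -- each the sum of 4-point Likert items, plus a composite equal to
the sum of all items.  Without access to a human cohort, a synthetic
generator plants a sparse linear dependence of each subscore on a few
behavioral features (plus noise) so that the downstream statistics have a
known ground truth.

The analysis stage mirrors the survey pipeline: Bonferroni-corrected Pearson
correlations between every (feature, score) pair, and nested cross-validated
Lasso regression -- an outer 4-fold split for scoring, an inner 3-fold split
on the training portion only for choosing the regularization strength, with
imputation and standardization fit strictly on training folds to prevent
data leakage.  The null hypothesis is characterized by re-running the whole
nested pipeline on player-identity-shuffled score tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SUBSCALES",
    "SCORE_COLUMNS",
    "AQScores",
    "PredictionReport",
    "synth_aq",
    "bonferroni_correlations",
    "nested_lasso_r2",
    "id_shuffle_null",
    "DEFAULT_ALPHAS",
]

#: subscale name -> number of 4-point Likert items (1..4 each)
SUBSCALES: dict[str, int] = {
    "social_skills": 8,
    "imagination": 8,
    "routine": 3,
    "switch": 4,
    "numbers_patterns": 5,
}
SCORE_COLUMNS: tuple[str, ...] = tuple(SUBSCALES) + ("composite",)

DEFAULT_ALPHAS: np.ndarray = np.logspace(-3, 1, 30)


@dataclass
class AQScores:
    """Synthetic AQ28 score table plus the planted ground truth."""

    scores: pd.DataFrame                   # player_id-indexed, 5 subscores + composite
    planted_weights: dict[str, pd.Series]  # subscale -> weights on active features

    def active_features(self, subscale: str) -> list[str]:
        return list(self.planted_weights[subscale].index)


def synth_aq(
    features: pd.DataFrame,
    k_active: int = 3,
    effect_size: float = 1.0,
    noise_sd: float = 0.1,
    rng: np.random.Generator | int | None = None,
    items_per_subscale: dict[str, int] | None = None,
) -> AQScores:
    """Generate trait scores with a planted sparse linear dependence on features.

    For each subscale, ``k_active`` features are chosen at random among the
    complete, non-constant columns; the latent score is
    ``effect_size * (Z w) + Normal(0, noise_sd)`` on standardized features Z
    with unit-magnitude random-sign weights, affinely mapped into the
    subscale's valid Likert-sum range [items, 4*items], clipped and rounded
    to integers.  The composite is the sum of the five subscores.
    """
    rng = np.random.default_rng(rng)
    items = dict(items_per_subscale or SUBSCALES)
    if set(items) != set(SUBSCALES):
        raise ValueError(f"items_per_subscale must cover exactly {set(SUBSCALES)}")

    X = features.to_numpy(float)
    usable = np.flatnonzero(~np.isnan(X).any(axis=0) & (np.nanstd(X, axis=0) > 0))
    if len(usable) < k_active:
        raise ValueError("not enough complete, non-constant features to plant on")

    cols: dict[str, np.ndarray] = {}
    planted: dict[str, pd.Series] = {}
    n = len(features)
    for name in SUBSCALES:
        idx = rng.choice(usable, size=k_active, replace=False)
        w = rng.choice([-1.0, 1.0], size=k_active)
        Z = (X[:, idx] - X[:, idx].mean(axis=0)) / X[:, idx].std(axis=0)
        latent = effect_size * (Z @ w) + rng.normal(0.0, noise_sd, size=n)
        lo, hi = items[name], 4 * items[name]
        spread = latent.std()
        scale = (hi - lo) / 6.0 / spread if spread > 0 else 0.0
        raw = (lo + hi) / 2.0 + scale * (latent - latent.mean())
        cols[name] = np.clip(np.rint(raw), lo, hi).astype(int)
        planted[name] = pd.Series(w, index=features.columns[idx])

    df = pd.DataFrame(cols, index=features.index)
    df["composite"] = df.sum(axis=1)
    return AQScores(scores=df, planted_weights=planted)


def bonferroni_correlations(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Pearson r and Bonferroni-corrected p for every (feature, score) pair.

    The correction multiplies each raw p by the family size -- by default the
    full joint search, n_features x n_scores -- capped at 1.  Zero-variance
    or insufficiently-observed features yield NaN rows.
    """
    if len(features) < 10:
        raise ValueError("need at least 10 players")
    score_cols = [c for c in scores.columns if c in SCORE_COLUMNS] or list(scores.columns)
    fam = family_size or features.shape[1] * len(score_cols)
    aligned = scores.loc[features.index]
    rows = []
    for fname, fvals in features.items():
        x = fvals.to_numpy(float)
        for sname in score_cols:
            y = aligned[sname].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x[ok], y[ok])
                p = min(1.0, p * fam)
            rows.append((fname, sname, r, p))
    return pd.DataFrame(rows, columns=["feature", "score", "r", "p_corrected"])


@dataclass
class PredictionReport:
    """Nested-CV Lasso performance for every subscore."""

    fold_r2: pd.DataFrame           # outer folds x scores (NaN = degenerate fold)
    median_r2: pd.Series
    mean_r2: pd.Series
    chosen_alphas: pd.DataFrame     # outer folds x scores
    nonzero_fraction: pd.DataFrame  # features x scores: fraction of folds with w != 0
    null_mean_r2: pd.DataFrame = field(default_factory=pd.DataFrame)  # realizations x scores


def _lasso_pipeline(alphas: np.ndarray, inner_folds: int, seed: int):
    from sklearn.impute import SimpleImputer
    from sklearn.linear_model import LassoCV
    from sklearn.model_selection import KFold
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler

    inner = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    return Pipeline([
        ("impute", SimpleImputer(strategy="median")),
        ("scale", StandardScaler()),
        ("lasso", LassoCV(alphas=alphas, cv=inner, max_iter=5000, tol=1e-3)),
    ])


def nested_lasso_r2(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    outer_folds: int = 4,
    inner_folds: int = 3,
    rng: np.random.Generator | int | None = None,
    alphas: np.ndarray = DEFAULT_ALPHAS,
) -> PredictionReport:
    """Nested cross-validated sparse regression of each score on the features.

    Per outer fold, the regularization strength is chosen by inner CV on the
    training portion only (imputation and standardization likewise fit on
    training data only), the model is refit and scored (R^2) on the held-out
    fold.  Median and mean R^2 across folds are both reported.  Folds with a
    constant target are flagged NaN and excluded from the summaries.
    """
    from sklearn.model_selection import KFold

    if len(features) < outer_folds * 2:
        raise ValueError("need at least 2 players per outer fold")
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(2**31))
    score_cols = [c for c in scores.columns if c in SCORE_COLUMNS] or list(scores.columns)
    y_all = scores.loc[features.index, score_cols]
    X = features.to_numpy(float)
    # drop all-NaN columns up front (median imputation undefined for them)
    col_ok = ~np.isnan(X).all(axis=0)
    feat_names = features.columns[col_ok]
    X = X[:, col_ok]

    outer = KFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    splits = list(outer.split(X))

    fold_r2 = pd.DataFrame(np.nan, index=range(outer_folds), columns=score_cols)
    chosen = pd.DataFrame(np.nan, index=range(outer_folds), columns=score_cols)
    nonzero = pd.DataFrame(0.0, index=feat_names, columns=score_cols)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sname in score_cols:
            y = y_all[sname].to_numpy(float)
            n_used = 0
            for f, (tr, te) in enumerate(splits):
                if np.std(y[tr]) == 0 or np.std(y[te]) == 0:
                    continue  # degenerate fold: flagged NaN
                pipe = _lasso_pipeline(alphas, inner_folds, seed + f)
                pipe.fit(X[tr], y[tr])
                fold_r2.loc[f, sname] = pipe.score(X[te], y[te])
                lasso = pipe.named_steps["lasso"]
                chosen.loc[f, sname] = lasso.alpha_
                nonzero[sname] += (lasso.coef_ != 0).astype(float)
                n_used += 1
            if n_used:
                nonzero[sname] /= n_used

    return PredictionReport(
        fold_r2=fold_r2,
        median_r2=fold_r2.median(),
        mean_r2=fold_r2.mean(),
        chosen_alphas=chosen,
        nonzero_fraction=nonzero,
    )


def id_shuffle_null(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    n_realizations: int = 100,
    rng: np.random.Generator | int | None = None,
    outer_folds: int = 4,
    inner_folds: int = 3,
    alphas: np.ndarray = DEFAULT_ALPHAS,
) -> pd.DataFrame:
    """Null distribution of mean R^2 from shuffled player identities.

    Each realization draws one permutation of the players, applies it to the
    whole score table (shared across all subscores within the realization),
    and re-runs the full nested pipeline.  Returns realizations x scores.
    """
    rng = np.random.default_rng(rng)
    aligned = scores.loc[features.index]
    rows = []
    for _ in range(n_realizations):
        perm = rng.permutation(len(aligned))
        shuffled = pd.DataFrame(
            aligned.to_numpy()[perm], index=aligned.index, columns=aligned.columns
        )
        rep = nested_lasso_r2(features, shuffled, outer_folds, inner_folds,
                              rng=int(rng.integers(2**31)), alphas=alphas)
        rows.append(rep.mean_r2)
    return pd.DataFrame(rows).reset_index(drop=True)
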