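"""Extract the 1521-dimensional behavioral feature vector from one game.

Categories: A = per-rule trace standard deviations (54), B = pairwise trace
correlations (1431), C = AI decision confidence by preceding condition (27),
D = outcome-transition probabilities (9).
"""
import numpy as np

from rrps import play_games
from rrps.features import (assemble_features, feature_metadata,
                           response_time_by_outcome, win_autocorrelation)

game = play_games("rs1", 1, n_rounds=300, seed=31)[0]
vec = assemble_features(game)
meta = feature_metadata().set_index("name")["category"]

print(f"feature vector length: {len(vec)}")
for cat in "ABCD":
    v = vec[meta == cat]
    print(f"  category {cat}: {len(v):4d} features, "
          f"{v.notna().sum():4d} defined, mean {np.nanmean(v):+.3f}")

print("\nresponse time by previous outcome (ms):")
print(response_time_by_outcome(game).round(1))

ac = win_autocorrelation(game, max_lag=5, n_shuffles=100, rng=32)
print("\nwin autocorrelation (with round-shuffle 95% band):")
print(ac.round(3))
# Lags outside [lo, hi] indicate temporal structure in the win sequence that
# round shuffling destroys -- e.g. the win streaks that follow rule switches.
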