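# Methods

This note documents the models and procedures implemented in `rrps`, the
parameter choices that matter, what the synthetic players do and do not
emulate, and the numerical conventions used where the design was genuinely
open.

## The game and the opponent

Games are 300 rounds of rock–paper–scissors under cyclic dominance (rock
beats scissors, paper beats rock, scissors beats paper). Hands are encoded
0/1/2 so that `(h+1) % 3` beats `h`; outcomes (win/tie/lose, player's
perspective) and transitions (downgrade/copy/upgrade relative to a reference
hand) are pure functions of hand differences modulo 3.

The opponent is a bank of three perceptrons, one per hand, each scoring a
13-dimensional input: one-hot codes of the last two player hands and the
last two AI hands (4 blocks of 3) plus a bias. Several of its details are
not dictated by the assay itself and are fixed here as follows:

* **Transfer and update**: logistic output, targets 1 (the hand the player
  actually produced) / 0 (the other two), delta rule
  `w ← w + η (target − σ(w·x)) x` applied every round from round 3 on.
* **Learning rate** η = 0.1 (configurable). Larger η speeds specialization
  and forgetting roughly symmetrically; the qualitative behavior of every
  statistic reported here is unchanged over η ∈ [0.02, 1].
* **Initialization**: zero weights. **Cold start** (rounds 1–2, no 2-round
  history): uniform random play, uniform confidence.
* **Action selection**: strict best response — the AI plays the hand that
  beats its argmax prediction; argmax ties break uniformly at random from
  the AI's private seeded RNG. No probability matching.
* **Confidence**: softmax of the three raw scores. Only relative score
  magnitudes are meaningful; softmax turns them into a normalized,
  scale-aware triple that the feature stage can average.

An additive (one-hot) perceptron cannot represent every function of the
previous (player, AI) hand pair — outcome-conditioned deterministic rules
are the 3-ary analogue of XOR — so exploitation of such players is an
empirical property of the closed loop, not a guarantee. In practice the AI
drives constant players to near-total loss and beats the deterministic
lag-1 players tested in the suite well above 50% in late rounds, while
staying at net zero against uniform-random play (the only unexploitable
strategy).

## Synthetic players (what the generator emulates)

Three families stand in for a human cohort:

* **NME**: uniform random each round. Used as the structure-free control;
  its games contain no planted rules and no switches.
* **Constant**: one hand forever; the exploitation sanity check.
* **Rule switchers (RS)**: play is sampled from a 3×3 lag-1 conditional
  probability matrix within one framework; at scheduled switch rounds the
  active matrix hops to a different member of the set (all three condition
  rows change simultaneously). Dominant rows are (0.9, 0.05, 0.05);
  rows without serial dependence are (1/3, 1/3, 1/3). Switch intervals are
  i.i.d. uniform integers on mean ± 3 (jitter configurable), mean 11 or 14
  rounds; the generator records ground-truth switch rounds in the game
  metadata. Round 1 has no lag-1 condition and is uniform random.

Two ruleset pairs ship with the package. `rs1` alternates a win-upgrade /
tie-copy ruleset (DCU|wtl; the lose row equiprobable) with an AI-hand-keyed
ruleset (beat the AI's rock, copy its scissors; its paper row equiprobable).
`rs2` alternates own-hand-keyed transitions (copy after rock, upgrade after
scissors) with outcome-keyed transitions of the AI's hand. Pairing rulesets
from *different* condition classes matters: when both rulesets live in the
same own-transition framework, closed-loop play collapses into short
deterministic chains that the AI memorizes across episodes, and the
advantage regained at a switch lasts only a single round. Layouts are fully
configurable (`make_rs_ruleset` accepts any per-row pattern and any A in
(1/3, 1]).

What the generator does **not** emulate: response-time structure tied to
outcomes (synthetic RTs are outcome-independent lognormals, median ≈ 850 ms),
drift or fatigue within a game, player-to-player heterogeneity of repertoire
beyond the two bundled layouts, and any dependence of trait scores on
behavior other than the explicitly planted linear one. Tests passing on
these simulations therefore validate the *pipeline* — detection calibration,
recovery of planted structure, leakage-free prediction — not claims about
real human cohorts.

## Repertoire detection

For each of the 54 rules, the dynamic conditional probability trace slides a
window over B = 3 consecutive occurrences of the rule's condition and
estimates #matching-actions / B, anchored at the round of the window's first
conditioning event; values between anchors are linearly interpolated (the
rule is assumed to persist in mind between conditioning events) and held at
the nearest estimate before the first / after the last anchor. With B = 3
the raw estimates take only the values {0, 1/3, 2/3, 1}. A rule whose
condition occurs fewer than B times has no trace and is excluded (never
imputed).

The rule shuffle score (RSS) counts rounds with trace strictly above 0.8.
Its null distribution comes from permuting the order of whole rounds —
within-round (player hand, AI hand, outcome) triples stay intact, temporal
structure is destroyed — and recomputing the statistic; one set of
permutations per game is shared across all 54 rules, which leaves each
rule's marginal test unchanged and saves a 54-fold recomputation. A rule is
in-repertoire when its RSS reaches the 98th percentile of its null, using
the strict percentile-of-score (fraction of null values strictly below);
with integer-valued statistics this keeps a value that merely ties the whole
null at the bottom, and holds the false-positive rate of the construction
near its nominal ~2% (the attainable floor is ~3/(n+1) at n shuffles, so
≥ 100 shuffles are needed for a meaningful 98% cut; the default is 200).

Thresholds 0.8 and 98 are conventions, not fitted quantities; moving them
within [0.75, 0.9] and [96, 99] changes which marginal rules are flagged
but not the separation between rule-switching and random players (asserted
in the suite).

## Switch detection

A ruleset change is invisible until the affected conditions recur and the
player's following actions reveal the new contingency, so detection must be
causal. The detector re-anchors the same window estimates at the round where
each window's evidence is complete — the action following the window's last
conditioning event — and scans in-repertoire traces for full swings:
monotone excursions of the (run-compressed) estimates from ≤ 0.2 to ≥ 0.8 or
back, completing within 9 rounds. The event is stamped at the swing's
completion (the first estimate at the far level). The 9-round span follows
from the estimator: a full 0→1 swing needs at least three window updates,
i.e. three conditioning events, ≈ 9 rounds at the typical one-in-three
conditioning rate; slower excursions are drift, not switches. Candidate
events across rules within 3 rounds merge to the earliest (one underlying
switch moves several conditional rows at once). All four constants
(low 0.2, high 0.8, span 9, merge 3) are configuration.

On simulated switchers this detector recovers essentially every game
(≥ 1 event in ~100% of RS(1)vAI(11) games, ~29 events/game) and the
ground-truth-triggered histogram of detections peaks at +4 to +5 rounds —
the waiting time for post-switch evidence. It is deliberately permissive and
produces false positives; on NME games (where any flagged rule is a false
positive of the 98th-percentile construction) roughly three-quarters of
games yield at least one event, ~5 events/game among them. A flagged
300-round trace almost always contains at least one full excursion, so the
NME event rate is driven almost entirely by the flag rate; a formal
change-point model would be the principled replacement and is out of scope.

## RSTW

RSTW(lag) = (#wins − #losses) / (#wins + #losses) at each signed lag from a
detected event, pooled over events and games; ties count in neither
numerator nor denominator, and lags with no win/loss events are undefined
(NaN), never zero-filled. Against the learning AI the curve rises toward the
detected change and sinks back as the AI re-adapts. Two timing facts
interact here: the advantage burst sits in the ~5 rounds *after the true
switch* (the AI's re-adaptation time in this closed loop), while detection
completes ~2–4 rounds after the true switch; relative to *detected* events
the elevation therefore appears at lags −4..0 rather than strictly after
lag 0. Against a non-learning NME opponent the same rule switcher shows a
flat curve — switching only pays against an opponent that was exploiting
the previous rule.

## Features

Per game, 1521 named features in four categories: (A) the population
standard deviation of each rule's trace (54); (B) Pearson correlations of
all unordered trace pairs (1431), each labeled 1–5 by the relation of the
two rules' frameworks and conditions, computed on the interpolated traces
without regard to repertoire status; (C) mean AI confidence components
following each of the 9 lag-1 conditions (27); (D) the 3×3
outcome-transition matrix (9). Traces are interpolated over the full game,
so a correlation pair overlaps on every round or not at all; pairs with an
undefined or constant member are missing, and missing features propagate as
NaN in stored tables — imputation (per-feature median) happens only inside
the prediction pipeline, fitted on training folds.

Test–retest stability correlates each feature across players between two
measurements and summarizes per category, against a null that permutes the
player identity of the second measurement (200 shuffles). Repertoire
patterns are clustered by agglomerative (Ward) clustering of the 54 RSS
percentiles, with a t-SNE embedding for visualization only (cluster labels
never depend on the embedding; perplexity adapts to small cohorts as
min(30, (n−1)/3)).

## Trait stage

The synthetic AQ28 generator plants, per subscale, a sparse linear
dependence on `k_active` (default 3) randomly chosen complete, non-constant
features: latent = effect_size · (Z w) + Normal(0, noise_sd) with
unit-magnitude random-sign weights on standardized features, affinely mapped
into the subscale's Likert-sum range [items, 4·items] (items per subscale
8/8/3/4/5 on a 1–4 scale, configurable), clipped and rounded to integers;
the composite is the sum of the five subscores. The planted weights are
returned for recovery tests. Rounding on the shortest subscale (3 items, 10
attainable levels) is itself a noise source.

Mass correlations are Pearson r with p-values Bonferroni-multiplied by the
full joint family (n_features × 6 scores = 9126 by default, configurable).
Prediction is a scikit-learn pipeline — median imputation, standardization,
`LassoCV` over a 30-point logarithmic α grid (1e−3..1e1) with an inner
3-fold split — fitted per outer fold on training data only and scored (R²)
on the held-out fold; both the median and the mean of the fold R² are
reported. Outer folds with a constant target are flagged NaN and excluded.
The identity-shuffle null permutes players of the whole score table (one
permutation shared by all subscores within a realization) and re-runs the
entire nested pipeline; its mean R² is almost always below zero, i.e. worse
than predicting the mean.

## Quality control

Mirroring screening of self-paced online play, a game fails engagement QC if
the mean response time is under 600 ms, if any run of identical player hands
exceeds 15, or if more than 10 inter-round gaps exceed 60 s (the "mean"
reading of the response-time filter is a choice; a per-round reading would
reject almost nobody or almost everybody depending on tail behavior).
Missing wall times skip the pause check and say so in the report.

## Problem sizes and determinism

The test suite and the acceptance script run the simulation studies at 50
games per condition with 100 round-shuffles per game (and 200 NME games for
the null-calibration check); these sizes put binomial noise on reported
fractions at the few-percent level while keeping the full suite in minutes
on one CPU. Every stochastic component draws from an explicit
`numpy.random.Generator`; batch helpers spawn per-game seeds from a single
root seed, so all outputs are bit-reproducible given the seed.

## Known limitations

* The switch detector is heuristic by construction; its false-positive
  behavior on structure-free games is documented above rather than tuned
  away. A latent-state switching model is the natural successor.
* The perceptron opponent is one concrete instantiation of "an online
  learner"; statistics that depend on its re-adaptation speed (the width
  and placement of the RSTW elevation) are specific to it.
* Simulated cohorts are homogeneous by design; population-level analyses
  (clustering of repertoire patterns, trait prediction) are validated on
  planted structure only.
* AI-confidence features require games recorded with per-round confidence;
  games from other sources lack category C and those features are missing,
  not zero.
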