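"""Detect which lag-1 rules a (simulated) player actually deploys.

For each of the 54 rules, the dynamic conditional probability trace is
summarized by its rounds above 0.8 (RSS) and compared with a round-shuffle
null; rules at the 98th percentile or higher are called in-repertoire.
"""
import numpy as np

from rrps import detect_repertoire, play_games
from rrps.simulate import bundled_ruleset_specs

game = play_games("rs1", 1, n_rounds=300, seed=11)[0]
results = detect_repertoire(game, B=3, thr=0.8, percentile_cut=98.0,
                            n_shuffles=200, rng=12)

planted = []
for rs in bundled_ruleset_specs("rs1"):
    cs, as_ = rs.framework.condition_symbols(), rs.framework.action_symbols()
    planted += [f"{rs.framework.name}:{as_[a]}|{cs[c]}" for c, a in rs.dominant_rules()]

print("rule                                    RSS   pctile  in-repertoire  planted")
for r in sorted(results, key=lambda r: -(r.rss)):
    if r.in_repertoire or r.rule.name in planted:
        print(f"{r.rule.name:38s} {r.rss:4d}  {r.percentile:6.1f}  "
              f"{str(r.in_repertoire):13s}  {'*' if r.rule.name in planted else ''}")
# Planted dominant rules should be flagged; extra flags are rules whose
# traces co-vary with the planted ones (the detector sees their episodes too).
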