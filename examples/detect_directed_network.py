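"""Detect a directed-dependency network with the prediction-ranked embedding.

Runs the greedy search once per target channel on a simulated Henon ring and
scores the detected network against the ground truth.
"""

from nuecte import (
    HenonConfig,
    NUEConfig,
    detect_network,
    ground_truth,
    score,
    simulate_henon,
    standardize,
)

data = standardize(simulate_henon(HenonConfig(Q=0.6, N=512, seed=7)))
cfg = NUEConfig(variant="msr", lambda_weight=1.0, gamma=0.0, seed=7)

result = detect_network(data, cfg)
print("detected adjacency (row drives column):")
print(result.adjacency)

for sel in result.per_target_selections:
    print(f"  target {sel.target}: selected {[tuple(c) for c in sel.selected]}"
          f"  ({sel.termination_reason})")

counts = score(result, ground_truth("henon"))
print(f"\nTP={counts.tp} TN={counts.tn} FP={counts.fp} FN={counts.fn}  "
      f"ACC={counts.acc:.1f}%  TPR={counts.tpr:.1f}%  TNR={counts.tnr:.1f}%")
# With Q=0.6 and 512 samples the six true couplings are recovered and the
# fourteen uncoupled ordered pairs are rejected in almost every realization.
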