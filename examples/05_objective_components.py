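"""The three objective components on worked numbers.

* supervised loss: cross-entropy of both predictor heads against labels;
* output-space matching: KL(p || q) pulling the two heads together;
* feature-space matching: central moment discrepancy (CMD, K=5) between
  the two drug-embedding distributions.
"""

import numpy as np

from ddilink.objectives import cmd_loss, output_matching_loss, supervised_loss, total_loss

uniform = np.array([0.5, 0.5])
confident = np.array([0.9, 0.1])

Ls = supervised_loss([(uniform, uniform, 1)])
print(f"uninformed prediction of one link: Ls = {Ls:.5f}  (= 2 ln 2, one ln 2 per head)")

Lom = output_matching_loss([(confident, uniform)])
print(f"disagreeing heads p={confident}, q={uniform}: Lom = {Lom:.5f}")
print(f"agreeing heads: Lom = {output_matching_loss([(confident, confident)]):.5f}")

rng = np.random.default_rng(0)
D = rng.normal(0.0, 1.0, size=(50, 8))    # intra-view embeddings
H = rng.normal(0.5, 1.5, size=(50, 8))    # inter-view embeddings, shifted + wider
print(f"CMD between mismatched embedding clouds: Lfm = {cmd_loss(D, H, K=5):.4f}")
print(f"CMD of a cloud against itself:           Lfm = {cmd_loss(D, D, K=5):.4f}")

b = total_loss(float(Ls), float(Lom), 0.75)
print(f"total with defaults alpha={b.alpha}, gamma={b.gamma}: "
      f"{b.Ls:.4f} + {b.alpha}*{b.Lom:.4f} + {b.gamma}*{b.Lfm:.4f} = {b.total:.4f}")
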