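"""Discrete-time hazards: survival function, risk score and the loss.

Walks the four-interval hazard model through a worked example: hazards
(0.1, 0.2, 0.3, 0.4) give survival S(2) = 0.9 * 0.8 * 0.7 and a risk score
of 1.0; the censoring-aware loss reproduces its two hand-computable cases.
"""

import numpy as np

from milsurv import loss_single, risk_score, survival_function

h = np.array([0.1, 0.2, 0.3, 0.4])
print("interval hazards:", h)
for r in range(4):
    print(f"  S({r}) = P(survive past interval {r}) = {survival_function(h, r):.4f}")
print(f"risk score (sum of hazards) = {risk_score(h):.1f}")

print(f"loss, event in interval 2:          "
      f"{loss_single(h, 2, 0, alpha=0.31):.6f}  (= -log(0.72 * 0.3))")
print(f"loss, censored in interval 1 (a=0.31): "
      f"{loss_single(h, 1, 1, alpha=0.31):.6f}  (= 0.69 * -log 0.72)")
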