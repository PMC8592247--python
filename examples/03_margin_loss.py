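"""The margin loss on class-embedding norms, term by term.

Each class k contributes
    Gamma_k = T_k max(0, 0.9 - ||nu_k||^2) + 0.5 (1-T_k) max(0, ||nu_k||^2 - 0.1)
so a present class is pushed until its squared norm reaches 0.9 and an
absent class until it falls to 0.1.
"""

import numpy as np

from cxrprior import MarginLossParams, margin_loss

params = MarginLossParams()
print(f"m+ = {params.m_plus}, m- = {params.m_minus}, lambda = {params.lam}\n")

cases = [
    ("present, squared norm at the m+ boundary", 0.9, 1),
    ("absent, squared norm at the m- boundary", 0.1, 0),
    ("present, squared norm 0.5 (term 0.9-0.5)", 0.5, 1),
    ("absent, squared norm 0.6 (term 0.5*(0.6-0.1))", 0.6, 0),
]
for label, q, t in cases:
    loss = margin_loss(np.array([np.sqrt(q)]), np.array([float(t)]), params)
    print(f"{label:48s} -> {loss:.3f}")

# A multi-label example: three classes, one present.
scores = np.array([0.95, 0.3, 0.7])
targets = np.array([1.0, 0.0, 0.0])
print(f"\n3-class example, scores {scores}, targets {targets}")
print(f"total loss {margin_loss(scores, targets, params):.4f}")
# Class 1 (present, q=0.9025) and class 2 (absent, q=0.09) are inside
# their margins; only class 3 (absent, q=0.49) is penalized.
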