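"""Average and modal controllability of a weighted network.

The adjacency is scaled to A = W / (1 + λ_max) so the linear dynamics
x(t+1) = A x(t) + B u(t) are stable; average controllability of a node is
the trace of its single-input controllability Gramian (≥ 1 always) and
modal controllability its ability to excite fast-decaying modes (in (0,1]).
"""

import numpy as np

from longconn import average_controllability, modal_controllability, normalize_adjacency

rng = np.random.default_rng(7)
w = rng.uniform(0, 2, size=(8, 8))
w = np.triu(w, 1)
w = w + w.T

a = normalize_adjacency(w)
print(f"normalization constant 1 + lambda_max = {a.normalization_constant:.4f}")

avg = average_controllability(a)
mod = modal_controllability(a)
strength = w.sum(axis=1)
print(f"{'node':>4} {'strength':>9} {'average':>9} {'modal':>9}")
for i in range(8):
    print(f"{i:>4} {strength[i]:9.3f} {avg[i]:9.4f} {mod[i]:9.4f}")

# Strongly connected hubs have high average but low modal controllability;
# weakly connected nodes show the opposite trade-off.
print("\ncorr(strength, average) = %.2f" % np.corrcoef(strength, avg)[0, 1])
print("corr(strength, modal)   = %.2f" % np.corrcoef(strength, mod)[0, 1])
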