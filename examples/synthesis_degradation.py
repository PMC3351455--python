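"""Open systems: synthesis and degradation via the ∗-graph.

A core graph whose vertices gain zero-order synthesis and first-order
degradation half-edges loses its conservation law; adding a single new
vertex '*' turns it back into an ordinary labelled graph whose MTT
kernel vector, normalised so x_* = 1, is the unique steady state.
"""

import numpy as np

from linfw import augment, check_balance, detect_unbounded, steady_state_syn_deg
from linfw.graph import build_graph, is_strongly_connected, numeric_laplacian
from linfw.syndeg import PartialGraph

core = build_graph(
    ["1", "2"],
    [("1", "2", 1.3), ("2", "1", 0.4)],
)
pg = PartialGraph(core, synthesis={"1": 0.9}, degradation={"2": 0.7})
aug = augment(pg)
print("Augmented graph vertices:", aug.vertices,
      "| strongly connected:", is_strongly_connected(aug))

x = steady_state_syn_deg(pg)
xv = {v: float(val) for v, val in x.items()}
print("\nSteady state from the ∗-graph MTT:", {v: round(c, 6) for v, c in xv.items()})

L = numeric_laplacian(core)
S = np.array([0.9, 0.0])
D = np.diag([0.0, 0.7])
xa = np.array([xv["1"], xv["2"]])
print("Residual of L.x + S - Delta.x:", np.abs(L @ xa + S - D @ xa).max())
print("Overall balance sum(s) = sum(d*x):", check_balance(pg, xv))
print("(inflow 0.9 = outflow 0.7 *", round(xv["2"], 6), ")")

# boundedness diagnosis: synthesis into a dead end accumulates forever
dead = PartialGraph(
    build_graph(["1", "2"], [("1", "2", 1.0)]), synthesis={"1": 1.0}
)
diag = detect_unbounded(dead)
print("\nSynthesis into an undegraded dead end:",
      "bounded" if diag["bounded"] else "UNBOUNDED", "-", diag["criterion"])
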