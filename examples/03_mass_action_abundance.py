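"""Effective relative abundances from an interaction matrix (mass action).

When visitation frequencies factorize as F_ij = x_i * x_j * c_ij, the
log-linear decomposition recovers the relative abundances x exactly; here
the true bee abundances are (0.2, 0.3, 0.5) and the estimates match.
"""

from datetime import date

import numpy as np

from beepac.abundance import estimate_abundances
from beepac.network_builder import DailyNetwork

x = np.array([0.2, 0.3, 0.5])  # bee relative abundances (truth)
y = np.array([0.1, 0.4, 0.2, 0.3])  # plant relative abundances (truth)
F = 200 * np.outer(x, y)  # constant preference, arbitrary scale

net = DailyNetwork(date(2020, 7, 1), 2020, ["Ba", "Bb", "Bc"], list("PQRS"), F)
est = estimate_abundances(net)
print("true bee abundances:     ", dict(zip(["Ba", "Bb", "Bc"], x)))
print("estimated bee abundances:", {k: round(v, 6) for k, v in est.bee_abundances.items()})
print("estimated plant abundances:", {k: round(v, 6) for k, v in est.plant_abundances.items()})
# Exact recovery: the estimator inverts the multiplicative structure, so
# the competition models can use abundance without the circularity of raw
# capture counts (which are themselves row sums of F).
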