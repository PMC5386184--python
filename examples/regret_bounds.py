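"""Regret upper bounds and their optimal learning rates.

Prints, for a pool of N=100 experts over t=50 steps with losses bounded by
epsilon=1: the standard forecaster's bound, the temporal bound (lambda=1/0.9)
before and after normalization onto the discounted scale, and the discounted
(CZ) bound — the normalized temporal bound is always the smaller of the two
(their ratio is exactly rho).  Then verifies on a random instance that the
observed regret stays below the bound at the bound-optimal rate.
"""
import numpy as np

from teadvice import ExpertPanel, TimeSeries, WeightScheme, run_online
from teadvice.regret import (
    BoundInputs,
    bound_comparison,
    optimal_bound,
    optimal_eta,
    regret_of,
)

inputs = BoundInputs(n_experts=100, t=50, epsilon=1.0, lambda_=1.0 / 0.9, rho=0.9)
print(f"standard bound:            {optimal_bound(inputs, 'standard'):8.3f}")
print(f"temporal bound (raw):      {optimal_bound(inputs, 'tea'):8.3f}")
cmp_ = bound_comparison(inputs)
print(f"temporal bound, normalized:{cmp_.tea_normalized:8.3f}")
print(f"discounted (CZ) bound:     {cmp_.cz:8.3f}")
print(f"normalized temporal <= CZ: {cmp_.tea_leq_cz} (ratio = rho = "
      f"{cmp_.tea_normalized / cmp_.cz:.3f})")

rng = np.random.default_rng(0)
panel = ExpertPanel(rng.uniform(0, 1, size=(100, 50)))
target = TimeSeries.from_values(rng.uniform(0, 1, size=50))
eta = optimal_eta(inputs, "tea")
result = run_online(panel, target,
                    WeightScheme("tea", lambda_=1.0 / 0.9, eta=eta))
print(f"\nsimulated exponential regret {regret_of(result.final_state):8.3f} "
      f"<= bound {optimal_bound(inputs, 'tea'):8.3f} at eta* = {eta:.4g}")
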