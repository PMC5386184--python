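"""Distribution prediction of PSA for a synthetic patient.

Simulates a small cohort from the piecewise-linear cell-population model,
treats one patient as the prediction target, fits each cohort member's rate
parameters to the target's first K=5 PSA measurements (initial-state fit),
weights the resulting model trajectories with the temporal scheme, and
prints the predicted median and upper quantile bands u(Q) for the next
measurement next to the actually simulated value.  A well-calibrated
predictor puts the observation below u(Q) with probability about Q.
"""
import warnings

import numpy as np

from teadvice import TimeSeries
from teadvice.distribution import (
    PSA_QUANTILE_LEVELS,
    fit_distribution_params,
    mixture_predict,
    quantile,
)
from teadvice.experts import model_experts
from teadvice.synthetic import CohortSpec, synthetic_cohort

warnings.filterwarnings("ignore", category=RuntimeWarning)

spec = CohortSpec(n_patients=10, n_points=6, spacing_range=(10.0, 25.0),
                  noise=0.05, seed=42)
_, patients = synthetic_cohort(spec)
target = patients[3].observed
K = 5
print(f"patient {patients[3].id}: PSA at first {K} visits "
      f"{np.round(target.values[:K], 2)} (days {np.round(target.times[:K])})")

rng = np.random.default_rng(1)
panel, _ = model_experts([p.params for p in patients], target, K,
                         target.times, rng=rng)
learning = TimeSeries(target.times[:K], target.values[:K])
scheme, sigma, state = fit_distribution_params(panel, learning)
print(f"selected decay lambda = {scheme.lambda_:.3f}, sigma = {sigma:.3f}")

mix = mixture_predict(state, panel, sigma, q=1)
print(f"\nnext visit (day {target.times[K]:.0f}): observed PSA "
      f"{target.values[K]:.2f}")
print(f"predicted median: {quantile(mix, 0.5):.2f}")
for Q in PSA_QUANTILE_LEVELS:
    print(f"  u({Q:5.3f}) = {quantile(mix, Q):7.2f}")
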