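"""Pairwise win tournament against the baselines.

Generates 20 short Henon-map targets, predicts each with the temporal,
discounted and standard schemes plus the persistence and running-average
baselines, and prints the pairwise target-win matrix (rows beat columns)
with the exact binomial significance thresholds for that many targets.
"""
import warnings

from teadvice import LossSpec, WeightScheme, run_online
from teadvice.evaluation import (
    average_predict,
    binomial_thresholds,
    persistence_predict,
    tournament,
    trace_from_run,
)
from teadvice.synthetic import ToyDatabaseSpec, toy_database, toy_target

warnings.filterwarnings("ignore", category=RuntimeWarning)

spec = ToyDatabaseSpec(m_param_sets=10, s_initial=30, length=40, seed=7)
_, panel = toy_database(spec)
targets = [toy_target(spec, seed=100 + i) for i in range(20)]
loss = LossSpec()


def online(scheme):
    return lambda tgt: trace_from_run(run_online(panel, tgt, scheme, loss))


methods = {
    "temporal": online(WeightScheme("tea", lambda_=1.0 / 0.9)),
    "discounted": online(WeightScheme("cz", rho=0.9)),
    "standard": online(WeightScheme("standard")),
    "persistence": persistence_predict,
    "average": average_predict,
}
result = tournament(methods, targets, burn_in=10)
print("target wins (row beat column):")
print(result.wins.to_string())
thr = binomial_thresholds(result.n_targets, 0.05)
print(f"\nfair-coin thresholds for n={thr.n}: a method is significantly "
      f"better above {thr.upper} wins, worse below {thr.lower}")
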