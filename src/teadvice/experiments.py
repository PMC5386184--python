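"""Protocol-level experiments on synthetic inputs.

Each function runs one self-contained study — regret-bound verification,
bound comparisons, calibration-by-construction, parameter recovery on a
synthetic PSA cohort, or the Henon database forecasting comparison — and
returns plain numbers.  All randomness flows from an explicit seed.
"""
from __future__ import annotations

import math
import warnings
from typing import Dict, Optional, Sequence

import numpy as np

from .core import ExpertPanel, LossSpec, TimeSeries, WeightScheme, init_state, run_online, update
from .distribution import MixturePrediction, mixture_predict, quantile, PSA_QUANTILE_LEVELS
from .evaluation import coverage_table
from .experts import model_experts
from .regret import BoundInputs, bound_comparison, optimal_bound, optimal_eta, regret_of
from .synthetic import CohortSpec, ToyDatabaseSpec, synthetic_cohort, toy_database, toy_target

__all__ = [
    "regret_bound_suite", "standard_limit_error", "bound_comparison_suite",
    "lambda_one_reduction_error", "quantile_identity_error",
    "coverage_by_construction", "parameter_recovery", "henon_comparison",
]


def regret_bound_suite(
    n_instances: int = 100,
    seed: int = 0,
    lambdas: Sequence[float] = (1.05, 1.11, 1.5),
    n_max: int = 50,
    t_max: int = 50,
) -> Dict[str, float]:
    """Random bounded-loss instances run at the bound-optimal learning rate.

    Returns the number of instances whose observed exponential regret
    exceeded the optimal upper bound (should be 0) and the largest
    regret/bound ratio.
    """
    rng = np.random.default_rng(seed)
    violations, max_ratio = 0, 0.0
    for _ in range(n_instances):
        n = int(rng.integers(2, n_max + 1))
        t = int(rng.integers(2, t_max + 1))
        lam = float(rng.choice(list(lambdas)))
        panel = ExpertPanel(rng.uniform(0.0, 1.0, size=(n, t)))
        target = TimeSeries.from_values(rng.uniform(0.0, 1.0, size=t))
        inputs = BoundInputs(n, t, 1.0, lambda_=lam)
        eta = optimal_eta(inputs, "tea")
        result = run_online(panel, target,
                            WeightScheme("tea", lambda_=lam, eta=eta))
        ratio = regret_of(result.final_state) / optimal_bound(inputs, "tea")
        max_ratio = max(max_ratio, ratio)
        if ratio > 1.0 + 1e-9:
            violations += 1
    return {"violations": violations, "max_ratio": max_ratio, "n": n_instances}


def standard_limit_error(
    t_grid: Sequence[int] = (1, 2, 5, 10, 50, 200),
    n_grid: Sequence[int] = (2, 5, 10, 100, 1000),
    lambda_near_one: float = 1.0 + 1e-9,
) -> float:
    """Max relative deviation of the temporal bound at lambda -> 1 from the
    standard-forecaster bound sqrt((t/2) ln N) at epsilon = 1."""
    worst = 0.0
    for t in t_grid:
        for n in n_grid:
            b = optimal_bound(BoundInputs(n, t, 1.0, lambda_=lambda_near_one), "tea")
            ref = math.sqrt(0.5 * t * math.log(n))
            worst = max(worst, abs(b - ref) / ref)
    return worst


def bound_comparison_suite(
    rho_grid: Sequence[float] = (0.5, 0.9, 0.99),
    t_grid: Sequence[int] = (2, 10, 50),
    n_grid: Sequence[int] = (2, 100),
    n_random: int = 1000,
    seed: int = 0,
) -> Dict[str, float]:
    """Normalized temporal bound vs the discounted bound over a fixed grid
    plus random draws; counts violations of tea <= cz (should be 0)."""
    cells = violations = 0
    for rho in rho_grid:
        for t in t_grid:
            for n in n_grid:
                cells += 1
                if not bound_comparison(BoundInputs(n, t, 1.0, rho=rho)).tea_leq_cz:
                    violations += 1
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        cells += 1
        inp = BoundInputs(
            int(rng.integers(2, 200)), int(rng.integers(1, 100)),
            float(rng.uniform(0.1, 5.0)), rho=float(rng.uniform(0.01, 0.999)),
        )
        if not bound_comparison(inp).tea_leq_cz:
            violations += 1
    return {"violations": violations, "n": cells}


def lambda_one_reduction_error(n_instances: int = 20, seed: int = 0) -> float:
    """Max absolute weight difference between the temporal scheme at
    lambda = 1 and the standard forecaster on shared inputs (exactly 0 when
    the reduction is bit-identical)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(2, 9))
        t = int(rng.integers(2, 11))
        panel = ExpertPanel(rng.uniform(0, 1, size=(n, t)))
        target = TimeSeries.from_values(rng.uniform(0, 1, size=t))
        eta = float(rng.uniform(0.1, 3.0))
        r1 = run_online(panel, target, WeightScheme("tea", lambda_=1.0, eta=eta))
        r2 = run_online(panel, target, WeightScheme("standard", eta=eta))
        for a, b in zip(r1.states, r2.states):
            worst = max(worst, float(np.abs(a.weights - b.weights).max()))
    return worst


def _random_mixture(rng) -> MixturePrediction:
    n = int(rng.integers(1, 7))
    w = rng.uniform(0.1, 1.0, size=n)
    return MixturePrediction(
        centers=rng.normal(0.0, 3.0, size=n), weights=w / w.sum(),
        sigma=float(rng.uniform(0.1, 2.0)),
    )


def quantile_identity_error(n_mixtures: int = 50, seed: int = 0) -> float:
    """Max |CDF(quantile(Q)) - Q| over random mixtures and the seven
    surveillance quantile levels plus the median."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_mixtures):
        mix = _random_mixture(rng)
        for Q in PSA_QUANTILE_LEVELS + (0.5, 0.025):
            u = quantile(mix, Q)
            worst = max(worst, abs(mix.cdf(u) - Q))
    return worst


def coverage_by_construction(
    n_subjects: int = 200,
    seed: int = 0,
    q_levels: Sequence[float] = PSA_QUANTILE_LEVELS,
) -> Dict[float, float]:
    """Calibration check: each subject's next observation is drawn from its
    own predictive mixture, so the fraction below u(Q) should sit near Q.

    Per subject a small expert panel is trained online for a few steps and
    the predictive mixture comes from the real prediction path
    (``mixture_predict``); returns the coverage proportion per Q level.
    """
    rng = np.random.default_rng(seed)
    loss = LossSpec()
    mixes, obs = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(n_subjects):
            n, t = int(rng.integers(2, 6)), int(rng.integers(3, 7))
            panel = ExpertPanel(rng.normal(1.0, 1.0, size=(n, t + 1)))
            target = TimeSeries.from_values(rng.normal(1.0, 1.0, size=t))
            result = run_online(
                panel, target, WeightScheme("tea", lambda_=1.3, eta=1.0), loss
            )
            mix = mixture_predict(result.final_state, panel,
                                  sigma=float(rng.uniform(0.2, 1.0)), q=1)
            comp = rng.choice(len(mix.centers), p=mix.weights)
            obs.append(float(mix.centers[comp] + rng.normal(0.0, mix.sigma)))
            mixes.append(mix)
    table = coverage_table({0: mixes}, {0: obs}, list(q_levels))
    return {float(Q): float(table.loc[Q, 0]) for Q in q_levels}


def parameter_recovery(
    n_replicates: int = 50,
    n_sets: int = 10,
    K: int = 5,
    seed: int = 0,
    n_starts: int = 20,
) -> Dict[str, float]:
    """Self-consistency on a noise-free synthetic PSA cohort.

    Each replicate samples a fresh cohort, picks one patient as the target,
    builds model experts by fitting every patient's rate set to the target's
    first K points, trains temporal weights on those points, and checks that
    the generating rate set carries the top weight.  Also reports the worst
    fit cost of the generating set (perfect-fit recovery).
    """
    loss = LossSpec()
    scheme = WeightScheme("tea", lambda_=1.5, tea_exponent="k", eta=1.0)
    successes, worst_cost = 0, 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for rep in range(n_replicates):
            spec = CohortSpec(n_patients=n_sets, noise=0.0, seed=seed + 7919 * rep)
            _, patients = synthetic_cohort(spec)
            rng = np.random.default_rng(seed + 104729 * rep + 1)
            r = int(rng.integers(n_sets))
            target = patients[r].observed
            panel, fits = model_experts(
                [p.params for p in patients], target, K, target.times,
                n_starts=n_starts, rng=rng,
            )
            worst_cost = max(worst_cost, fits[r].cost)
            state = init_state(panel)
            for t in range(1, K + 1):
                state = update(state, panel.advice_at(t),
                               float(target.values[t - 1]), loss, scheme, 0.0)
            successes += int(np.argmax(state.weights) == r)
    return {
        "recovery_rate": successes / n_replicates,
        "worst_generating_fit_cost": worst_cost,
        "n": n_replicates,
    }


def henon_comparison(
    n_replicates: int = 20,
    m_param_sets: int = 20,
    s_initial: int = 50,
    length: int = 60,
    rho: float = 0.9,
    burn_in: int = 10,
    seed: int = 0,
) -> Dict[str, float]:
    """Temporal vs standard expert advice on Henon-map databases.

    Per replicate: a fresh expert database (parameters uniform in
    a in [1.3, 1.4], b in [0.1, 0.2]) and a target at (a, b) = (1.35, 0.15);
    both schemes run online with the shared auto learning rate and are scored
    by the standard accumulated absolute error after the burn-in.  Returns
    the fraction of replicates the temporal scheme wins (ties count as wins
    for neither side being worse: error_tea <= error_std).
    """
    loss = LossSpec()
    wins = 0
    err_tea_total = err_std_total = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for rep in range(n_replicates):
            spec = ToyDatabaseSpec(
                m_param_sets=m_param_sets, s_initial=s_initial, length=length,
                seed=seed + 31337 * rep,
            )
            _, panel = toy_database(spec)
            target = toy_target(spec)
            r_tea = run_online(panel, target,
                               WeightScheme("tea", lambda_=1.0 / rho),
                               loss, burn_in=burn_in)
            r_std = run_online(panel, target, WeightScheme("standard"),
                               loss, burn_in=burn_in)
            y = target.values[r_tea.steps - 1]
            e_tea = float(np.abs(r_tea.predictions - y).sum())
            e_std = float(np.abs(r_std.predictions - y).sum())
            err_tea_total += e_tea
            err_std_total += e_std
            wins += int(e_tea <= e_std)
    return {
        "tea_win_fraction": wins / n_replicates,
        "mean_error_tea": err_tea_total / n_replicates,
        "mean_error_standard": err_std_total / n_replicates,
        "n": n_replicates,
    }
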