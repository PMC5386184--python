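"""Evaluation protocol: baselines, pairwise win tournaments, exact binomial
significance thresholds, loss-accumulation curves, and coverage tables.

The comparison protocol mirrors a forecasting shoot-out on many short
targets: for each pair of methods and each target, count the time points at
which one method's per-point loss is strictly smaller than the other's
(excluding an initial burn-in, default 10 points, where no learning history
exists); a method wins the target when it is better at more than half the
compared points.  Aggregated win counts over n targets are judged against
exact two-sided binomial critical values under the fair-coin null, e.g.
531/469 for n = 1000 and 71/49 for n = 120 at the 95% level.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binom

from .core import (
    ExpertPanel,
    LossSpec,
    TimeSeries,
    WeightScheme,
    coefficient,
    run_online,
)
from .distribution import MixturePrediction, quantile

__all__ = [
    "PredictionTrace", "PairwiseResult", "Tournament", "ThresholdPair",
    "persistence_predict", "average_predict", "pairwise_wins", "tournament",
    "binomial_thresholds", "loss_curves", "coverage_table", "trace_from_run",
]


@dataclass(frozen=True)
class PredictionTrace:
    """One-step predictions aligned with 1-based target steps."""

    steps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        steps = np.asarray(self.steps, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if steps.shape != values.shape or steps.ndim != 1:
            raise ValueError("steps and values must be matching 1-D arrays")
        object.__setattr__(self, "steps", steps)
        object.__setattr__(self, "values", values)


def trace_from_run(result) -> PredictionTrace:
    """Adapt a ``run_online`` result to a PredictionTrace."""
    return PredictionTrace(steps=result.steps, values=result.predictions)


def persistence_predict(target: TimeSeries) -> PredictionTrace:
    """Forecast each next value as the current value."""
    if len(target) < 2:
        raise ValueError("persistence needs at least 2 points")
    return PredictionTrace(
        steps=np.arange(2, len(target) + 1), values=target.values[:-1]
    )


def average_predict(target: TimeSeries) -> PredictionTrace:
    """Forecast each next value as the running mean of all past values."""
    if len(target) < 2:
        raise ValueError("average prediction needs at least 2 points")
    running = np.cumsum(target.values[:-1]) / np.arange(1, len(target))
    return PredictionTrace(steps=np.arange(2, len(target) + 1), values=running)


@dataclass(frozen=True)
class PairwiseResult:
    points_a: int
    points_b: int
    ties: int
    winner: Optional[str]  # "a", "b", or None

    @property
    def n_compared(self) -> int:
        return self.points_a + self.points_b + self.ties


def pairwise_wins(
    pred_a: PredictionTrace,
    pred_b: PredictionTrace,
    target: TimeSeries,
    burn_in: int = 10,
    loss: LossSpec = LossSpec(),
) -> PairwiseResult:
    """Count compared points won by each method on one target.

    Points are compared on the intersection of the two traces' steps after
    the burn-in; per-point ties count toward neither method, and a method
    wins the target only with strictly more than half the compared points.
    """
    common, ia, ib = np.intersect1d(pred_a.steps, pred_b.steps, return_indices=True)
    keep = common > burn_in
    if not keep.any():
        raise ValueError("no compared points remain after the burn-in")
    steps = common[keep]
    if steps.max() > len(target):
        raise ValueError("prediction steps extend beyond the target")
    y = target.values[steps - 1]
    la = loss.loss(pred_a.values[ia[keep]], y)
    lb = loss.loss(pred_b.values[ib[keep]], y)
    pa = int(np.sum(la < lb))
    pb = int(np.sum(lb < la))
    n = len(steps)
    winner = "a" if pa > n / 2 else ("b" if pb > n / 2 else None)
    return PairwiseResult(points_a=pa, points_b=pb, ties=n - pa - pb, winner=winner)


@dataclass(frozen=True)
class Tournament:
    """Pairwise target-win counts; ``wins.loc[A, B]`` is the number of
    targets on which method A beat method B."""

    wins: pd.DataFrame
    pair_ties: pd.DataFrame
    n_targets: int


MethodMap = Mapping[str, Callable[[TimeSeries], PredictionTrace]]


def tournament(
    methods: MethodMap,
    targets: Sequence[TimeSeries],
    burn_in: int = 10,
    loss: LossSpec = LossSpec(),
) -> Tournament:
    """Run every method on every target and tally pairwise target wins."""
    names = list(methods)
    if len(names) < 2:
        raise ValueError("a tournament needs at least 2 methods")
    if len(targets) == 0:
        raise ValueError("a tournament needs at least 1 target")
    wins = pd.DataFrame(0, index=names, columns=names)
    ties = pd.DataFrame(0, index=names, columns=names)
    for target in targets:
        traces = {name: fn(target) for name, fn in methods.items()}
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                res = pairwise_wins(traces[a], traces[b], target, burn_in, loss)
                if res.winner == "a":
                    wins.loc[a, b] += 1
                elif res.winner == "b":
                    wins.loc[b, a] += 1
                else:
                    ties.loc[a, b] += 1
                    ties.loc[b, a] += 1
    return Tournament(wins=wins, pair_ties=ties, n_targets=len(targets))


@dataclass(frozen=True)
class ThresholdPair:
    """Two-sided binomial critical values under the fair-coin null: win
    counts strictly above ``upper`` (below ``lower``) are significant."""

    n: int
    alpha: float
    lower: int
    upper: int


def binomial_thresholds(n: int, alpha: float = 0.05) -> ThresholdPair:
    """Exact-tail critical values for Binomial(n, 1/2).

    ``upper`` is the smallest c with P(X > c) <= alpha/2, so "more than c
    wins" is significant; by the null's symmetry ``lower = n - upper``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    c = int(binom.isf(alpha / 2.0, n, 0.5))
    while binom.sf(c, n, 0.5) > alpha / 2.0:
        c += 1
    while c > 0 and binom.sf(c - 1, n, 0.5) <= alpha / 2.0:
        c -= 1
    return ThresholdPair(n=n, alpha=alpha, lower=n - c, upper=c)


def loss_curves(
    panels: Mapping[int, ExpertPanel],
    target: TimeSeries,
    schemes: Mapping[str, WeightScheme],
    loss: LossSpec = LossSpec(),
    burn_in: int = 0,
) -> pd.DataFrame:
    """Accumulated losses of each scheme's forecaster vs expert-pool size.

    For each panel size and scheme the online run's emitted predictions are
    scored twice: the *standard* accumulated loss sums the per-step losses,
    and the *exponential* accumulated loss weights step k by the scheme's own
    coefficient a_k(T).  For the standard scheme the two curves coincide.
    """
    rows = []
    for n_experts in sorted(panels):
        panel = panels[n_experts]
        for name, scheme in schemes.items():
            res = run_online(panel, target, scheme, loss, burn_in=burn_in)
            y = target.values[res.steps - 1]
            per_step = loss.loss(res.predictions, y)
            coeffs = np.array(
                [coefficient(res.scheme, int(k), len(target)) for k in res.steps]
            )
            rows.append(
                {
                    "method": name,
                    "n_experts": n_experts,
                    "standard_loss": float(per_step.sum()),
                    "exponential_loss": float(per_step @ coeffs),
                }
            )
    return pd.DataFrame(rows)


def coverage_table(
    predictions: Mapping[int, Sequence[MixturePrediction]],
    observations: Mapping[int, Sequence[float]],
    q_levels: Sequence[float],
) -> pd.DataFrame:
    """Fraction of next-point observations below the predicted u(Q) band.

    ``predictions[K]`` holds one next-point predictive mixture per subject
    whose learning period used K points, and ``observations[K]`` the matching
    next observed values.  Rows are Q levels, columns are K values; a
    well-calibrated predictor puts the fraction near Q.
    """
    q_levels = list(q_levels)
    k_values = sorted(predictions)
    if not k_values:
        raise ValueError("no subjects supplied")
    table = pd.DataFrame(index=q_levels, columns=k_values, dtype=float)
    for K in k_values:
        mixes = list(predictions[K])
        obs = np.asarray(observations[K], dtype=float)
        if len(mixes) != len(obs) or len(mixes) == 0:
            raise ValueError(f"K={K}: predictions and observations must align")
        for Q in q_levels:
            bands = np.array([quantile(m, Q) for m in mixes])
            table.loc[Q, K] = float(np.mean(obs < bands))
    return table
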