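"""Distribution prediction: Gaussian mixtures over expert advice.

Assuming each expert's point advice is disturbed by normally distributed
error with common standard deviation sigma, the forecaster's predictive
distribution at step t+q is the weight-mixture of Gaussians centered on the
experts' advice:

    p(u) = sum_i w_{i,t} * N(u; f_{i,t+q}, sigma**2).

Its mean equals the point prediction; quantiles u_t(Q) solve CDF(u) = Q and
summarize the prediction as one-sided bands (e.g. the seven levels 97.5%,
87.5%, 75%, 65%, 60%, 55%, 52.5% used for PSA surveillance).

Two data-driven parameters are selected on the learning prefix of a target:
the decay rate lambda (grid search over (1, 2), scored by the absolute
error of the one-step prediction of the final learning point) and sigma
(either the final-point absolute error, or — for PSA — the mean absolute
error between the distribution median and the observation over the learning
period, computed with a provisional sigma and refined once).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .core import (
    ExpertPanel,
    ForecastState,
    LossSpec,
    TimeSeries,
    WeightScheme,
    init_state,
    point_predict,
    update,
)

__all__ = [
    "MixturePrediction", "QuantileRequest", "mixture_predict", "quantile",
    "select_lambda", "estimate_sigma", "fit_distribution_params",
    "default_lambda_grid", "PSA_QUANTILE_LEVELS",
]

#: One-sided band levels used for PSA surveillance (upper half of the
#: predictive distribution).
PSA_QUANTILE_LEVELS = (0.975, 0.875, 0.75, 0.65, 0.60, 0.55, 0.525)


@dataclass(frozen=True)
class MixturePrediction:
    """Weighted Gaussian mixture with common standard deviation."""

    centers: np.ndarray
    weights: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if centers.ndim != 1 or centers.shape != weights.shape or len(centers) == 0:
            raise ValueError("centers and weights must be matching 1-D arrays")
        if not np.all(np.isfinite(centers)):
            raise ValueError("centers must be finite")
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "weights", weights / weights.sum())

    @property
    def mean(self) -> float:
        return float(self.weights @ self.centers)

    def pdf(self, u) -> np.ndarray:
        u = np.atleast_1d(np.asarray(u, dtype=float))
        comp = norm.pdf(u[:, None], loc=self.centers, scale=self.sigma)
        out = comp @ self.weights
        return out if out.size > 1 else float(out[0])

    def cdf(self, u) -> np.ndarray:
        u = np.atleast_1d(np.asarray(u, dtype=float))
        comp = norm.cdf(u[:, None], loc=self.centers, scale=self.sigma)
        out = comp @ self.weights
        return out if out.size > 1 else float(out[0])

    @property
    def median(self) -> float:
        return quantile(self, 0.5)


@dataclass(frozen=True)
class QuantileRequest:
    """A probability level Q in (0, 1)."""

    Q: float

    def __post_init__(self) -> None:
        if not 0.0 < self.Q < 1.0:
            raise ValueError("Q must lie strictly between 0 and 1")


def mixture_predict(
    state: ForecastState, panel: ExpertPanel, sigma: float, q: int = 1
) -> MixturePrediction:
    """Predictive mixture at step t+q: centers are the surviving experts'
    advice, weights are the state's weights renormalized over survivors."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if q < 1:
        raise ValueError("q must be >= 1")
    step = state.t + q
    if step > panel.n_steps:
        raise ValueError(f"step {step} beyond panel length {panel.n_steps}")
    mask = panel.active(step)
    if not mask.any():
        raise ValueError(f"no expert has horizon >= step {step}")
    w = state.weights[mask]
    return MixturePrediction(
        centers=panel.advice[mask, step - 1], weights=w / w.sum(), sigma=sigma
    )


def quantile(mix: MixturePrediction, req: Union[QuantileRequest, float]) -> float:
    """The value u with mixture-CDF(u) = Q, by bracketing and bisection.

    The bracket [min(c) + sigma*z_Q, max(c) + sigma*z_Q] is rigorous because
    the mixture CDF is pinched between the component CDFs of the extreme
    centers; the root is then polished to 1e-10.
    """
    Q = req.Q if isinstance(req, QuantileRequest) else float(req)
    if not 0.0 < Q < 1.0:
        raise ValueError("Q must lie strictly between 0 and 1")
    z = norm.ppf(Q)
    lo = mix.centers.min() + mix.sigma * z
    hi = mix.centers.max() + mix.sigma * z
    if hi - lo < 1e-14:
        return float(lo)
    flo = mix.cdf(lo) - Q
    fhi = mix.cdf(hi) - Q
    # mathematically flo <= 0 <= fhi; roundoff can push an endpoint onto the
    # root's far side by ~1e-16, in which case the endpoint IS the quantile
    # to far better than the CDF tolerance
    if flo >= 0:
        return float(lo)
    if fhi <= 0:
        return float(hi)
    return float(brentq(lambda u: mix.cdf(u) - Q, lo, hi, xtol=1e-10, maxiter=200))


def default_lambda_grid(n: int = 100) -> np.ndarray:
    """n equally spaced decay-rate candidates strictly inside (1, 2)."""
    return np.linspace(1.0, 2.0, n + 2)[1:-1]


def _train_prefix(
    panel: ExpertPanel,
    series: TimeSeries,
    scheme: WeightScheme,
    loss: LossSpec,
    n_steps: int,
) -> Tuple[ForecastState, np.ndarray]:
    """Run predict-then-update over steps 1..n_steps; return the final state
    and the one-step predictions made at each step."""
    state = init_state(panel)
    preds = np.empty(n_steps)
    for t in range(1, n_steps + 1):
        preds[t - 1] = point_predict(state, panel, q=1)
        state = update(
            state, panel.advice_at(t), float(series.values[t - 1]),
            loss, scheme, preds[t - 1], active=panel.active(t),
        )
    return state, preds


def select_lambda(
    panel: ExpertPanel,
    learning_series: TimeSeries,
    scheme_template: WeightScheme,
    loss: LossSpec = LossSpec(),
    grid: Optional[Sequence[float]] = None,
) -> float:
    """Grid-search the decay rate lambda on the learning prefix.

    For each candidate, weights are trained on all learning points but the
    last, the final point is predicted one step ahead, and the candidate
    minimizing the absolute error wins; ties break toward the smallest
    lambda.
    """
    K = len(learning_series)
    if K < 2:
        raise ValueError("learning series needs at least 2 points")
    grid = default_lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    if len(grid) == 0 or np.any(grid <= 1.0) or np.any(grid >= 2.0):
        raise ValueError("lambda grid must be nonempty and inside (1, 2)")
    best_lam, best_err = None, np.inf
    for lam in np.sort(grid):
        scheme = replace(scheme_template, variant="tea", lambda_=float(lam))
        scheme = scheme.resolved(panel.n_experts, K - 1, loss.epsilon)
        state, _ = _train_prefix(panel, learning_series, scheme, loss, K - 1)
        pred = point_predict(state, panel, q=1)
        err = abs(pred - float(learning_series.values[K - 1]))
        if err < best_err:  # strict: ties keep the smaller lambda
            best_lam, best_err = float(lam), err
    return best_lam


def estimate_sigma(
    mode: str,
    predictions: Sequence[float],
    observations: Sequence[float],
    sigma_min: float = 1e-6,
) -> float:
    """Error-based spread of the predictive mixture.

    ``final_point``: absolute error at the last learning point.
    ``psa_learning_mean``: mean absolute error between the distribution
    medians and the observations over the whole learning period (the
    ``predictions`` argument then holds those medians).
    A floor ``sigma_min`` guards the degenerate perfect-fit case.
    """
    predictions = np.asarray(predictions, dtype=float)
    observations = np.asarray(observations, dtype=float)
    if predictions.shape != observations.shape or len(predictions) == 0:
        raise ValueError("predictions and observations must align and be nonempty")
    if mode == "final_point":
        sigma = abs(predictions[-1] - observations[-1])
    elif mode == "psa_learning_mean":
        sigma = float(np.mean(np.abs(predictions - observations)))
    else:
        raise ValueError(f"unknown sigma mode {mode!r}")
    return max(float(sigma), sigma_min)


def fit_distribution_params(
    panel: ExpertPanel,
    learning_series: TimeSeries,
    scheme_template: WeightScheme = WeightScheme(variant="tea", lambda_=1.5,
                                                tea_exponent="k"),
    loss: LossSpec = LossSpec(),
    grid: Optional[Sequence[float]] = None,
    sigma_mode: str = "psa_learning_mean",
    sigma_min: float = 1e-6,
) -> Tuple[WeightScheme, float, ForecastState]:
    """Select lambda and sigma on the learning prefix and train the weights.

    Returns the resolved scheme (with the selected lambda), the estimated
    sigma, and the state trained on the full learning period.  The
    learning-mean sigma rule needs distribution medians during learning, so
    a provisional sigma from the final-point rule seeds one refinement pass.
    """
    K = len(learning_series)
    lam = select_lambda(panel, learning_series, scheme_template, loss, grid)
    scheme = replace(scheme_template, variant="tea", lambda_=lam)
    scheme = scheme.resolved(panel.n_experts, K, loss.epsilon)

    # Provisional sigma: absolute error of the one-step prediction of the
    # final learning point (weights trained on the earlier points).
    state_prefix, _ = _train_prefix(panel, learning_series, scheme, loss, K - 1)
    p_last = point_predict(state_prefix, panel, q=1)
    sigma = estimate_sigma(
        "final_point", [p_last], [learning_series.values[-1]], sigma_min
    )

    state, _ = _train_prefix(panel, learning_series, scheme, loss, K)
    if sigma_mode == "psa_learning_mean":
        # One refinement pass: medians of the per-step predictive mixtures
        # during learning, under the provisional sigma.
        medians = np.empty(K)
        s = init_state(panel)
        for t in range(1, K + 1):
            mix = mixture_predict(s, panel, sigma, q=1)
            medians[t - 1] = quantile(mix, 0.5)
            s = update(
                s, panel.advice_at(t), float(learning_series.values[t - 1]),
                loss, scheme, medians[t - 1], active=panel.active(t),
            )
        sigma = estimate_sigma(
            "psa_learning_mean", medians, learning_series.values[:K], sigma_min
        )
    elif sigma_mode != "final_point":
        raise ValueError(f"unknown sigma mode {sigma_mode!r}")
    return scheme, sigma, state
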