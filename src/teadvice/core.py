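"""Weighting engines and point prediction for forecasting with expert advice.

Three weighting schemes share one update rule.  Each expert *i* accumulates a
coefficient-weighted loss

    L_{i,t} = sum_{k=1}^{t} a_k(t) * l(f_{i,k}, y_k)

and receives the normalized weight ``w_{i,t} ∝ exp(-eta * L_{i,t})``.  The
coefficient distinguishes the schemes:

* ``standard``  -- a_k(t) = 1 (the classical exponentially weighted average
  forecaster);
* ``tea``       -- a_k(t) = lambda**(k-1) or lambda**k with lambda > 1, so the
  loss at recent steps dominates (temporal expert advice, suited to unstable
  dynamics that quickly forget their past);
* ``cz``        -- a_k(t) = rho**(t-k-1) with 0 < rho < 1, the
  Chernov--Zhdanov discounted scheme.

Point predictions are weight-averaged expert advice ``q`` steps ahead.

Time steps are 1-based in every formula-facing argument; storage is 0-based
internally.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "TimeSeries", "ExpertPanel", "LossSpec", "WeightScheme", "ForecastState",
    "RunResult", "init_state", "coefficient", "update", "point_predict",
    "run_online",
]


@dataclass(frozen=True)
class TimeSeries:
    """Ordered scalar observations ``y_k`` at strictly increasing times ``t_k``."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if len(times) != len(values):
            raise ValueError(
                f"length mismatch: {len(times)} times vs {len(values)} values"
            )
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(values)) or not np.all(np.isfinite(times)):
            raise ValueError("times and values must be finite")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "TimeSeries":
        """Series indexed by 1-based integer steps."""
        values = np.asarray(values, dtype=float)
        return cls(np.arange(1, len(values) + 1, dtype=float), values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ExpertPanel:
    """N experts x T steps advice matrix ``f_{i,t}``.

    ``advice[i, t-1]`` is expert *i*'s advice at (1-based) step *t*.  Experts
    built from finite windows end early; ``horizons[i]`` is the last valid
    step for expert *i* and entries beyond it are NaN.
    """

    advice: np.ndarray
    horizons: Optional[np.ndarray] = None
    ids: Optional[tuple] = None

    def __post_init__(self) -> None:
        advice = np.asarray(self.advice, dtype=float)
        if advice.ndim != 2 or advice.shape[0] < 1:
            raise ValueError("advice must be a nonempty N x T matrix")
        object.__setattr__(self, "advice", advice)
        if self.horizons is None:
            horizons = np.full(advice.shape[0], advice.shape[1], dtype=int)
        else:
            horizons = np.asarray(self.horizons, dtype=int)
            if horizons.shape != (advice.shape[0],):
                raise ValueError("horizons must have one entry per expert")
            if np.any(horizons < 1) or np.any(horizons > advice.shape[1]):
                raise ValueError("horizons must lie in [1, T]")
        object.__setattr__(self, "horizons", horizons)
        for i in range(advice.shape[0]):
            if not np.all(np.isfinite(advice[i, : horizons[i]])):
                raise ValueError(
                    f"expert {i}: non-finite advice within horizon {horizons[i]}"
                )
        if self.ids is not None:
            ids = tuple(self.ids)
            if len(ids) != advice.shape[0]:
                raise ValueError("ids must have one entry per expert")
            object.__setattr__(self, "ids", ids)

    @property
    def n_experts(self) -> int:
        return self.advice.shape[0]

    @property
    def n_steps(self) -> int:
        return self.advice.shape[1]

    def active(self, t: int) -> np.ndarray:
        """Boolean mask of experts whose horizon covers 1-based step ``t``."""
        if not 1 <= t:
            raise ValueError(f"step must be >= 1, got {t}")
        return self.horizons >= t

    def advice_at(self, t: int) -> np.ndarray:
        """Advice column at 1-based step ``t`` (NaN beyond an expert's horizon)."""
        if not 1 <= t <= self.n_steps:
            raise ValueError(f"step {t} outside panel range [1, {self.n_steps}]")
        return self.advice[:, t - 1]


@dataclass(frozen=True)
class LossSpec:
    """Convex loss with a nominal bound ``epsilon`` on its magnitude.

    ``epsilon`` enters the regret bounds and the optimal learning rate; it is
    configuration, never estimated from data.  Losses exceeding ``epsilon``
    only warn (biomarker series routinely exceed the conventional epsilon=1).
    """

    kind: str = "absolute"
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("absolute", "squared"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")

    def loss(self, x, y):
        """Elementwise loss l(x, y); warns when it exceeds epsilon."""
        x = np.asarray(x, dtype=float)
        if self.kind == "absolute":
            out = np.abs(x - y)
        else:
            out = (x - y) ** 2
        if np.any(out > self.epsilon):
            warnings.warn(
                f"loss exceeds the configured bound epsilon={self.epsilon}; "
                "regret bounds assume losses within epsilon",
                RuntimeWarning,
                stacklevel=2,
            )
        return out


EtaLike = Union[float, str, Callable[[int], float], None]


@dataclass(frozen=True)
class WeightScheme:
    """Variant and parameters of the weighting coefficient and learning rate.

    ``eta`` may be a positive constant, a callable mapping the 1-based step to
    a rate (a schedule), or ``"auto"`` to use the bound-optimal rate resolved
    at run time from (N, T, epsilon, lambda/rho).
    """

    variant: str = "tea"
    lambda_: Optional[float] = None
    tea_exponent: str = "k_minus_1"
    rho: Optional[float] = None
    eta: EtaLike = "auto"

    def __post_init__(self) -> None:
        if self.variant not in ("standard", "tea", "cz"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "tea":
            if self.lambda_ is None or not self.lambda_ >= 1.0:
                raise ValueError("tea requires lambda >= 1")
            if self.tea_exponent not in ("k_minus_1", "k"):
                raise ValueError("tea_exponent must be 'k_minus_1' or 'k'")
        if self.variant == "cz":
            if self.rho is None or not 0.0 < self.rho < 1.0:
                raise ValueError("cz requires rho in (0, 1)")
        if isinstance(self.eta, (int, float)) and not self.eta >= 0:
            raise ValueError("eta must be nonnegative")

    def eta_at(self, t: int) -> float:
        if self.eta is None or (isinstance(self.eta, str) and self.eta == "auto"):
            raise ValueError(
                "eta is 'auto'; resolve it first (run_online does this) or "
                "set a concrete value"
            )
        if callable(self.eta):
            eta = float(self.eta(t))
            if eta < 0:
                raise ValueError(f"eta schedule returned {eta} < 0 at step {t}")
            return eta
        return float(self.eta)

    def resolved(self, n_experts: int, horizon: int, epsilon: float) -> "WeightScheme":
        """Return a copy with ``eta='auto'`` replaced by the classical rate
        sqrt(8 ln N / (epsilon**2 T)).

        The rate depends only on the pool size, the horizon and the loss
        range — not on the decay parameter.  The per-variant bound-optimal
        rate shrinks like lambda**-(t-1) to guard the worst case of the
        exponential regret, which freezes the weights for most of the run
        and is the wrong scale for prediction; the coefficient growth is the
        tracking mechanism, not a scale to cancel.  Bound-optimal rates
        remain available through the regret module.
        """
        if not (self.eta is None or (isinstance(self.eta, str) and self.eta == "auto")):
            return self
        from .regret import BoundInputs, optimal_eta  # local: avoid cycle

        inputs = BoundInputs(
            n_experts=max(n_experts, 2), t=max(horizon, 1), epsilon=epsilon,
        )
        return replace(self, eta=optimal_eta(inputs, "standard"))


def coefficient(scheme: WeightScheme, k: int, t: int) -> float:
    """Loss coefficient ``a_k(t)`` for step ``k`` when the current step is ``t``.

    standard -> 1;  tea -> lambda**(k-1) or lambda**k;  cz -> rho**(t-k-1).
    """
    if not 1 <= k <= t:
        raise ValueError(f"step k={k} outside [1, t={t}]")
    if scheme.variant == "standard":
        return 1.0
    if scheme.variant == "tea":
        exp = k - 1 if scheme.tea_exponent == "k_minus_1" else k
        try:
            return float(scheme.lambda_) ** exp
        except OverflowError:
            return math.inf
    return float(scheme.rho) ** (t - k - 1)


@dataclass(frozen=True)
class ForecastState:
    """Accumulated losses and normalized log-weights after ``t`` updates."""

    t: int
    expert_losses: np.ndarray
    predictor_loss: float
    log_weights: np.ndarray

    @property
    def n_experts(self) -> int:
        return len(self.expert_losses)

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)


def init_state(panel: ExpertPanel) -> ForecastState:
    """State at t=0: zero losses, uniform weights 1/N."""
    n = panel.n_experts
    return ForecastState(
        t=0,
        expert_losses=np.zeros(n),
        predictor_loss=0.0,
        log_weights=np.full(n, -math.log(n)),
    )


def _normalize_log_weights(losses: np.ndarray, eta: float) -> np.ndarray:
    # Only loss differences matter; shifting by the minimum keeps
    # exp(-eta * L) representable even when eta * lambda**(t-1) is huge.
    shifted = -eta * (losses - losses.min())
    return shifted - logsumexp(shifted)


def update(
    state: ForecastState,
    advice_col: np.ndarray,
    y: float,
    loss: LossSpec,
    scheme: WeightScheme,
    prediction: float,
    active: Optional[np.ndarray] = None,
) -> ForecastState:
    """One online step: charge losses for the revealed ``y``, reweight.

    ``prediction`` is the forecaster's own output made *before* seeing ``y``;
    its loss accumulates identically into ``predictor_loss``.  Experts outside
    ``active`` (expired windows) incur no loss this step.
    """
    t = state.t + 1
    advice_col = np.asarray(advice_col, dtype=float)
    if advice_col.shape != (state.n_experts,):
        raise ValueError("advice_col must have one entry per expert")
    if active is None:
        active = np.ones(state.n_experts, dtype=bool)
    if not np.isfinite(y):
        raise ValueError(f"non-finite observation at step {t}")
    if not np.all(np.isfinite(advice_col[active])):
        raise ValueError(f"non-finite advice among active experts at step {t}")

    step_losses = np.zeros(state.n_experts)
    step_losses[active] = loss.loss(advice_col[active], y)
    pred_loss = float(loss.loss(prediction, y))

    if scheme.variant == "cz":
        # Incremental form of sum_k rho**(t-k-1) l_k: L <- rho*L + l_t/rho.
        rho = float(scheme.rho)
        expert_losses = rho * state.expert_losses + step_losses / rho
        predictor_loss = rho * state.predictor_loss + pred_loss / rho
    else:
        a = coefficient(scheme, t, t)
        if not math.isfinite(a):
            lam = scheme.lambda_
            t_max = int(1 + math.log(np.finfo(float).max) / math.log(lam))
            raise OverflowError(
                f"coefficient lambda**(t-1) overflowed at step t={t} "
                f"(lambda={lam}); usable horizon is about {t_max} steps"
            )
        expert_losses = state.expert_losses + a * step_losses
        predictor_loss = state.predictor_loss + a * pred_loss
    if not np.all(np.isfinite(expert_losses)):
        raise OverflowError(
            f"accumulated loss overflowed at step t={t}; reduce lambda or the horizon"
        )

    eta = scheme.eta_at(t)
    return ForecastState(
        t=t,
        expert_losses=expert_losses,
        predictor_loss=predictor_loss,
        log_weights=_normalize_log_weights(expert_losses, eta),
    )


def point_predict(state: ForecastState, panel: ExpertPanel, q: int = 1) -> float:
    """Weighted average of advice ``q`` steps ahead: sum_i w_i f_{i,t+q}.

    Experts whose horizon ends before step ``t+q`` are excluded and the
    weights renormalized over the survivors.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    step = state.t + q
    if step > panel.n_steps:
        raise ValueError(f"step {step} beyond panel length {panel.n_steps}")
    mask = panel.active(step)
    if not mask.any():
        raise ValueError(f"no expert has horizon >= step {step}")
    w = state.weights[mask]
    return float(w @ panel.advice[mask, step - 1] / w.sum())


@dataclass(frozen=True)
class RunResult:
    """Trace of an online run: predictions for steps after the burn-in, and
    the forecaster state after every update (aligned with steps 1..T)."""

    steps: np.ndarray
    predictions: np.ndarray
    states: tuple
    scheme: WeightScheme

    @property
    def final_state(self) -> ForecastState:
        return self.states[-1]


def run_online(
    panel: ExpertPanel,
    target: TimeSeries,
    scheme: WeightScheme,
    loss: LossSpec = LossSpec(),
    burn_in: int = 0,
) -> RunResult:
    """Iterate predict-then-update over the target series.

    At every step the one-step prediction is formed before the observation is
    revealed; predictions during the first ``burn_in`` steps still train the
    weights but are not emitted in the trace.
    """
    T = len(target)
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    if T < burn_in + 1:
        raise ValueError(f"target length {T} shorter than burn_in + 1 = {burn_in + 1}")
    if panel.n_steps < T:
        raise ValueError(
            f"panel has {panel.n_steps} steps but target needs {T}"
        )
    scheme = scheme.resolved(panel.n_experts, T, loss.epsilon)

    state = init_state(panel)
    states = []
    preds = []
    for t in range(1, T + 1):
        pred = point_predict(state, panel, q=1)
        if t > burn_in:
            preds.append(pred)
        state = update(
            state,
            panel.advice_at(t),
            float(target.values[t - 1]),
            loss,
            scheme,
            pred,
            active=panel.active(t),
        )
        states.append(state)
    return RunResult(
        steps=np.arange(burn_in + 1, T + 1),
        predictions=np.asarray(preds),
        states=tuple(states),
        scheme=scheme,
    )
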