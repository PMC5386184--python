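"""Regret definitions, optimal learning rates, and regret upper bounds.

For a scheme with per-step coefficients ``a_k`` and losses bounded in an
interval of width ``epsilon``, the Hoeffding route of the classical
exponentially-weighted-forecaster analysis gives, for any learning rate
``eta > 0``,

    regret(t) <= ln(N)/eta + (eta * epsilon**2 / 8) * S(t),
    S(t) = sum_{k=1}^{t} a_k**2,

where the regret is the forecaster's coefficient-weighted accumulated loss
minus that of the best single expert.  Minimizing over ``eta`` yields

    eta* = sqrt(8 ln N / (epsilon**2 S(t))),
    B*   = epsilon * sqrt(S(t) * ln(N) / 2).

The coefficient sum specializes per scheme:

* standard: S = t, recovering the textbook bound epsilon*sqrt((t/2) ln N);
* temporal (a_k = lambda**(k-1), lambda > 1): S = (lambda**(2t)-1)/(lambda**2-1);
* discounted (a_k(t) = rho**(t-k-1), 0 < rho < 1):
  S = rho**(-2) * (1-rho**(2t))/(1-rho**2).

The temporal and discounted bounds live on different loss scales; with
matched decay (lambda = 1/rho) multiplying the temporal bound by
``rho**(t-1)`` puts them on the same scale, and the normalized temporal
bound is then strictly smaller than the discounted one for every
0 < rho < 1 (their ratio is exactly rho).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import ForecastState

__all__ = [
    "BoundInputs", "RegretReport", "regret_of", "coeff_square_sum",
    "regret_bound", "optimal_eta", "optimal_bound", "normalized_tea_bound",
    "bound_comparison", "BoundComparison", "regret_report",
]

_VARIANTS = ("standard", "tea", "cz")


@dataclass(frozen=True)
class BoundInputs:
    """Quantities entering a regret bound: pool size N, horizon t, loss range
    epsilon, and the decay parameter of the scheme (lambda or rho)."""

    n_experts: int
    t: int
    epsilon: float = 1.0
    lambda_: Optional[float] = None
    rho: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_experts < 2:
            raise ValueError("bounds require at least 2 experts")
        if self.t < 1:
            raise ValueError("horizon t must be >= 1")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if self.lambda_ is not None and not self.lambda_ >= 1.0:
            raise ValueError("lambda must be >= 1")
        if self.rho is not None and not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (0, 1)")


@dataclass(frozen=True)
class RegretReport:
    """Observed regret against the scheme's optimal upper bound."""

    regret: float
    bound: float
    eta_used: float
    satisfied: bool


def regret_of(state: ForecastState) -> float:
    """Forecaster's accumulated loss minus the best expert's, both in the
    scheme's own (coefficient-weighted) accumulation."""
    return float(state.predictor_loss - state.expert_losses.min())


def _geometric_sum(log_r: float, t: int) -> float:
    """sum_{k=0}^{t-1} r**k computed as expm1 ratio, stable for r near 1."""
    if log_r == 0.0:
        return float(t)
    try:
        return math.expm1(t * log_r) / math.expm1(log_r)
    except OverflowError:
        return math.inf


def coeff_square_sum(inputs: BoundInputs, variant: str) -> float:
    """S(t) = sum of squared coefficients a_k(t)**2 for the scheme."""
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    t = inputs.t
    if variant == "standard":
        return float(t)
    if variant == "tea":
        if inputs.lambda_ is None:
            raise ValueError("tea bound requires lambda")
        return _geometric_sum(2.0 * math.log(inputs.lambda_), t)
    if inputs.rho is None:
        raise ValueError("cz bound requires rho")
    rho = inputs.rho
    return _geometric_sum(2.0 * math.log(rho), t) / rho**2


def regret_bound(inputs: BoundInputs, variant: str, eta: float) -> float:
    """Two-term regret upper bound ln(N)/eta + eta*epsilon**2*S(t)/8."""
    if not eta > 0:
        raise ValueError("eta must be positive")
    s = coeff_square_sum(inputs, variant)
    return math.log(inputs.n_experts) / eta + eta * inputs.epsilon**2 * s / 8.0


def optimal_eta(inputs: BoundInputs, variant: str = "tea") -> float:
    """Learning rate minimizing the two-term bound:
    eta* = sqrt(8 ln N / (epsilon**2 S(t)))."""
    s = coeff_square_sum(inputs, variant)
    return math.sqrt(8.0 * math.log(inputs.n_experts) / (inputs.epsilon**2 * s))


def optimal_bound(inputs: BoundInputs, variant: str = "tea") -> float:
    """Minimized regret upper bound B* = epsilon*sqrt(S(t) ln(N)/2)."""
    s = coeff_square_sum(inputs, variant)
    return inputs.epsilon * math.sqrt(s * math.log(inputs.n_experts) / 2.0)


def normalized_tea_bound(inputs: BoundInputs) -> float:
    """Temporal-scheme optimal bound rescaled by rho**(t-1) (lambda = 1/rho)
    onto the discounted scheme's loss scale."""
    if inputs.rho is None:
        raise ValueError("normalization requires rho")
    lambda_ = inputs.lambda_ if inputs.lambda_ is not None else 1.0 / inputs.rho
    if abs(lambda_ * inputs.rho - 1.0) > 1e-9:
        raise ValueError(
            f"normalization requires lambda = 1/rho; got lambda={lambda_}, "
            f"rho={inputs.rho}"
        )
    tea_inputs = BoundInputs(
        n_experts=inputs.n_experts, t=inputs.t, epsilon=inputs.epsilon,
        lambda_=lambda_,
    )
    # rho**(t-1) * sqrt(S_tea) computed in log space: for small rho and large
    # t the two factors over/underflow individually but not combined.
    log_s = _log_geometric_sum(2.0 * math.log(lambda_), inputs.t)
    log_bound = (
        math.log(inputs.epsilon)
        + (inputs.t - 1) * math.log(inputs.rho)
        + 0.5 * (log_s + math.log(math.log(inputs.n_experts) / 2.0))
    )
    # Cross-check against the direct product when it is representable.
    direct = optimal_bound(tea_inputs, "tea") * inputs.rho ** (inputs.t - 1)
    if math.isfinite(direct) and direct > 0:
        return direct
    return math.exp(log_bound)


def _log_geometric_sum(log_r: float, t: int) -> float:
    if log_r == 0.0:
        return math.log(t)
    # log( (r**t - 1)/(r - 1) ) for r > 1
    return (
        t * log_r + math.log1p(-math.exp(-t * log_r))
        - log_r - math.log1p(-math.exp(-log_r))
    )


@dataclass(frozen=True)
class BoundComparison:
    tea_normalized: float
    cz: float
    tea_leq_cz: bool


def bound_comparison(inputs: BoundInputs) -> BoundComparison:
    """Normalized temporal bound vs the discounted (CZ) bound at matched
    decay; the normalized temporal bound is smaller for every rho in (0,1)."""
    if inputs.rho is None or not 0.0 < inputs.rho < 1.0:
        raise ValueError("comparison requires rho in (0, 1)")
    tea_norm = normalized_tea_bound(inputs)
    cz = optimal_bound(inputs, "cz")
    return BoundComparison(tea_normalized=tea_norm, cz=cz, tea_leq_cz=tea_norm <= cz)


def regret_report(state: ForecastState, inputs: BoundInputs, variant: str,
                  eta: float) -> RegretReport:
    """Bundle an observed run's regret with the scheme's optimal bound."""
    r = regret_of(state)
    b = optimal_bound(inputs, variant)
    return RegretReport(regret=r, bound=b, eta_used=eta, satisfied=r <= b + 1e-9)
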